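# Methods

## Model

A genome is a multiset of linear chromosomes; a chromosome is a sequence
of signed synteny-block identifiers over Σ = {1..n}, equivalent to its
reflection (reversed order, flipped signs). Genes may be duplicated:
`mult(π, x)` counts occurrences of `x` in any orientation, `t(π, e)`
counts how often extremity `e` (the tail `x_t` or head `x_h`) is a
chromosome end. The ancestor ρ is restricted: two chromosomes are either
disjoint (no shared identifier) or identical, and every identifier in Σ
occurs — the situation of, e.g., a diploid karyotype from which a tumor
genome evolved. The descendant π is unrestricted.

Eleven operation kinds transform genomes: reversal, transposition,
inverted transposition, fusion, fission, translocation, tandem
duplication, transposition duplication, deletion, chromosome duplication
and chromosome deletion. All have weight 1 except the three
transposition-like kinds (weight 2), because a transposition needs two
double-cut-and-join (DCJ) steps while the other content-preserving
operations need one. The task: find a low-weight operation sequence from
ρ to π. The search runs backwards — π is sorted into ρ by inverse
operations, which is equivalent and exploits ρ's structure — and the
found inverse sequence is inverted and reversed into a forward scenario.
Every scenario is replayed during tests; replay must reproduce π exactly.

Because a chromosome equals its reflection, the transposition
duplication carries a strand flag for its source segment: reading the
segment from the reflected strand is the same biological event. Without
the flag some inverse duplications would be inexpressible after
canonicalization.

## Breakpoint graph and metrics

Vertices are the 2n extremities. Gray edges join extremities adjacent in
ρ (a set — identical copies add nothing); black edges join extremities
adjacent in π (a multiset), except that a black edge is suppressed when
an endpoint carries no gray edge, i.e. is a telomere of ρ. A black edge
(v, v) is a loop (created by `x -x` patterns). `C` counts connected
components (singletons included), `L_i` loop-carrying vertices per
component. 1-bridges are black edges whose removal (of one copy) splits
a component; 2-bridges are pairs of non-bridge black edges whose joint
removal does. Bridges are found with a lowpoint DFS on the multigraph;
tests cross-check against brute-force edge removal on networkx graphs.

Incorrect telomeres:

    T(ρ, π) = Σ_e max(0, t(ρ,e) − t(π,e)) + Σ_{e : t(ρ,e) = 0} t(π,e)

— ancestor telomeres still missing from π, plus telomeres of π that the
ancestor never has. Since no single operation moves T by more than 2,
and no operation that decreases T can also repair the graph term, the
distance is bounded below by

    lb(ρ, π) = ceil(T/2) + CL,   CL = c(ρ) − C + Σ_i ceil(L_i / 2)

where c(ρ) = C(ρ, ρ) (for a valid ancestor, n plus the number of
distinct chromosomes; the graph form is used so the same code serves the
fallback's rescaled ancestor, where a chromosome's ploidy may drop to
zero). `lb(ρ, ρ) = 0`.

The bound can vanish before the genomes agree, so ties are broken by an
auxiliary distance that is zero exactly at π = ρ:

    τ(ρ, π) = m + [2·ia(ρ,ρ) + ta(ρ,ρ)] − [2·ia(ρ,π) + ta(ρ,π)]
    m = 4 · Σ_x |mult(ρ,x) − mult(π,x)|

with `ia` the per-occurrence count of inner adjacencies and `ta` the
telomere adjacencies capped per extremity at t(ρ,e) (surplus identical
telomeres do not score). Each extremity occurrence contributes at most 1
to `2·ia + ta`, so a surplus copy of an element pays at least
4 − 2 = 2 — this makes τ strictly positive off the identity. All metric
arithmetic is integer.

## The greedy search

Each round scores candidate inverse operations by
σ = (Δlb, Δτ), compared lexicographically, and applies the best
candidate: first the best with Δlb ≥ 1, otherwise the best with a
positive score (Δlb = 0, Δτ ≥ 1), otherwise the fallback. Candidates are
*generated* structurally and *scored* exactly by applying them and
recomputing the metrics (verify-by-recompute); generation decides only
what is worth scoring. Families:

- **Adjacency joins.** For every gray edge (u, w) with both extremities
  exposed at a breakpoint junction or a chromosome end, the DCJ-type
  operation joining them (reversal, translocation with optional
  reflection, fusion; a transposition when both sites are on one
  molecule). Cuts happen only at breakpoints or ends, so no existing
  adjacency is split.
- **Fissions** at breakpoint junctions (in particular between two
  ancestor telomeres, which scores (1, 2)).
- **Surplus fusions** consuming two telomeres the ancestor lacks, and
  **telomere swaps** trading a surplus telomere for a missing one.
- **Duplicate removals** (inverse duplications): identical chromosome
  copies; maximal adjacent repeats (inverse tandem duplication); maximal
  chunks of surplus runs that still have an exact copy elsewhere on
  either strand (inverse transposition duplication), found by
  seed-and-extend and re-derived every round.
- **Insertions** (inverse deletions) of maximal under-represented
  ancestor segments, placed next to an occurrence of a neighbouring
  element so that a new junction is an ancestor adjacency; whole missing
  chromosomes enter as chromosome insertions. Inserted content is always
  a contiguous ancestor substring.
- **Bridge-driven DCJs** (generated on demand when nothing else lowers
  the bound): cuts on 1-bridges paired with ends or same-component
  breakpoints, and on 2-bridge pairs.

Ties between equal scores break deterministically (operation-kind rank,
then parameters), so runs are reproducible without a seed. Per-family
caps (`SorterConfig`) bound the candidate count per round; they trade
scenario quality against runtime, never correctness.

## Fallback

If no candidate has a positive score the fallback finishes the run:
(a) per ancestor chromosome, every element whose multiplicity in the
current genome trails the chromosome's maximum is raised by inserting
maximal ancestor segments (inverse deletions, placed without creating
new breakpoints); (b) ρ is rescaled by chromosome duplications/deletions
into ρ′ with matching multiplicities — these become the first forward
operations of the scenario; (c) the greedy loop runs to ρ′ with all
content-changing operations forbidden. In that regime a positive-score
operation always exists while the genomes differ (any breakpoint admits
an adjacency-creating operation or a (1, 2) fission), so the loop
terminates; a safety budget derived from the initial (lb, τ) potential
guards against implementation bugs and raises loudly instead of looping.

## Simulator

`make_ancestor` builds c equal-sized chromosomes partitioning Σ,
replicated per ploidy; the four presets are dataset1 (16 chromosomes of
ploidy 2, 64 elements — a yeast-like genome), dataset2 (12 × ploidy 2,
36), dataset3 (5 × ploidy 2, 60 — plant-like) and dataset4 (5
chromosomes, 200 elements, ploidies 1,1,2,2,2 — two sex chromosomes plus
three diploid autosomes of a *Drosophila*-scale map). `mutate` draws
operation kinds i.i.d. (uniform over the eleven kinds by default) and,
given the kind, draws uniformly over all valid parameterizations on the
current genome; it stops before the accumulated weight would exceed
w = α·n, so the realized weight is w or w − 1 and is reported as the
true weight. Same config and seed ⇒ identical output.

What the generator does not emulate: biologically calibrated operation
probabilities (the uniform mix is a benchmark convention, not biology),
hotspots, length-biased rearrangements, or nucleotide-level detail.
Passing tests therefore certify the algorithm under the benchmark
conditions, not on real karyotypes. One structural consequence worth
knowing: because segment endpoints are uniform over each chromosome,
expected duplication length grows with chromosome length, and at α = 1.0
on dataset4 the descendant inflates to roughly three times the
ancestor's content. Sorting such genomes is dominated by inverse
duplications; the measured sorting weight at α = 1.0 settles around a
median of ≈ 210 over 10 replicates (individual replicates range from
≈ 55 on deletion-heavy histories to ≈ 440), independent of the true
weight 200. With shorter duplication segments the plateau drops, since
surplus content then leaves in fewer, cleaner pieces.

## Exhaustive oracle

`exact_distance` runs a bidirectional uniform-cost search: forward from
ρ over all parameterizations of the eleven kinds, backward from π over
all inverse operations, meeting in the middle (default radius 2 + 2 =
weight 4). Inverse deletions are restricted to contiguous ancestor
substrings — the same restriction the sorter obeys — so the value is
exact for that restricted model and an upper bound on the unrestricted
optimum, which keeps sandwich checks `lb ≤ d ≤ sorter weight` sound.
Only toy alphabets (n ≤ 4–6) are feasible.

## Numerical and design choices

- Chromosomes are stored canonically (the smaller of sequence and
  reflection under id-then-orientation order); operations address
  chromosomes by canonical key, and identical copies are
  interchangeable, so parameters stay stable across multiset edits.
- Positions are 0-based, half-open over element indices; cut positions
  range over 0..len. Operations that would empty a chromosome delete it;
  operations that would empty the genome are rejected.
- The sorter rebuilds metrics from scratch for every candidate (no
  incremental graph updates); a per-round scan plus a compact union-find
  over gray-component roots keeps one evaluation at O(genome size).
- Benchmark band: in the dataset2 trend check (α = 0.5, 20 replicates)
  the mean calculated weight must lie between the mean lower bound and
  the mean true weight and within 25% of the latter; the band reflects
  run-to-run spread of a greedy heuristic at small n, chosen before
  measurement.

## Known limitations

- The greedy score is myopic: removals of fragmented surplus copies cost
  weight 2 per fragment, and no lookahead reassembles a copy before
  removing it unless the reassembling step itself scores.
- Scenario weight, not biological plausibility, is optimized; the
  uniform weights are a mathematical convention.
- Circular chromosomes are not modelled (DCJ circular intermediates
  exist only transiently inside the two-step transposition realization).
- The oracle's restriction to ancestor-substring insertions can
  overestimate the unrestricted optimum on contrived inputs.
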