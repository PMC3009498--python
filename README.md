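# dupsort

Reconstruction of weighted rearrangement scenarios between
multichromosomal genomes **with duplicated gene content**.

Classical genome rearrangement algorithms assume every gene occurs
exactly once per genome. Real genomes — plant genomes, polyploids,
cancer karyotypes evolving out of a diploid chromosome set — are full of
duplicated content, and the events that shape them include duplications
and deletions of segments of arbitrary size. `dupsort` sorts an
ancestral genome ρ into a descendant π using reversals, transpositions,
inverted transpositions, fusions, fissions, translocations, tandem
duplications, transposition duplications, deletions, and chromosome
duplications/deletions. All operations have weight 1 except the
transposition-like ones (weight 2, since they need two double-cut-and-
join steps); the goal is a low total weight. The ancestor must satisfy
one constraint, natural for karyotype applications: its chromosomes are
pairwise disjoint or identical, and every synteny block occurs.

The method (searching from π back to ρ by inverse operations):

* an **extended breakpoint graph** on the 2n block extremities — gray
  edges from ρ's adjacencies, a black multiset from π's, suppressed at
  ancestor telomeres; with components `C`, loops `L_i`, and 1-/2-bridges;
* a **lower bound** on the weighted distance,
  `lb = ceil(T/2) + c(ρ) − C + Σ ceil(L_i/2)`, where `T` counts
  incorrect telomeres;
* an auxiliary distance **τ** (multiplicity mismatch plus missing
  adjacencies) that is zero exactly when the genomes coincide;
* a **greedy loop** scoring each candidate inverse operation by
  `σ = (Δlb, Δτ)` lexicographically, and a **guaranteed-terminating
  fallback** (multiplicity equalization, ploidy rescaling,
  content-preserving finish) for the rare states where no candidate
  scores;
* a **simulator** that generates benchmark (ρ, π) pairs with a known
  true scenario weight `w = α·n`, including four named dataset presets
  at yeast- to *Drosophila*-scale synteny-block counts.

See `docs/methods.md` for the precise definitions and design choices.

## Worked example

```python
from dupsort import Genome, genome_metrics, sort

rho = Genome([(1, 2, 3), (4, 5, 6)])          # ancestor: two chromosomes
pi  = Genome([(1, -2, 3, 5, 6), (4, 5, 6), (4, 5, 6)], n=6)

m = genome_metrics(rho, pi)
print("lb =", m.lb, " tau =", m.tau, " T =", m.T, " C =", m.C)

scenario = sort(rho, pi)
print("total weight:", scenario.total_weight)
for op in scenario.operations:
    print(" ", op.kind.value, op.params())
assert scenario.replay(Genome(rho.chromosomes, n=6)) == pi
```

prints

```
lb = 2  tau = 19  T = 1  C = 7
total weight: 4
  chromosome_duplication {'chrom': [4, 5, 6]}
  reversal {'chrom': [1, 2, 3], 'start': 1, 'end': 2}
  transposition_duplication {'chrom': [4, 5, 6], 'chrom_b': [1, -2, 3], 'start': 1, 'end': 3, 'insert': 3}
```

Reading: the pair is at least 2 operations apart (`lb = 2`); the sorter
found a weight-4 scenario — duplicate the second chromosome, invert
block 2, and copy the segment `(5 6)` onto the end of the first
chromosome by a transposition duplication (weight 2) — and replaying
those three operations on ρ reproduces π exactly. `τ = 19` quantifies
how far the pair is from identity even where the lower bound is blind
(τ reaches 0 only at ρ = π).

The same is available from a shell:

```sh
dupsort simulate --preset dataset2 --alpha 0.4 --seed 7 -o /tmp/sim
dupsort sort -a /tmp/sim.rho.txt -d /tmp/sim.pi.txt -o /tmp/scenario.tsv --json-metrics
dupsort metrics -a /tmp/sim.rho.txt -d /tmp/sim.pi.txt
dupsort bench --preset dataset2 --alphas 0.1,0.3,0.5 --replicates 5 --seed 1 -o /tmp/bench.csv
```

Genome files hold one chromosome per line as signed integers (see
`docs/methods.md`); `examples/` contains short narrative scripts for
each capability.

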