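"""Greedy reconstruction of a rearrangement scenario between two genomes.

The search runs in the inverse direction -- from the descendant ``pi``
back to the ancestor ``rho`` -- because the ancestor's structure
(chromosomes pairwise disjoint or identical) gives the breakpoint graph
its useful properties.  Every inverse step is scored by
``sigma = (delta_lb, delta_tau)``, the drop it causes in the lower bound
and in the auxiliary distance, compared lexicographically.  Each round
applies the best operation that decreases the lower bound; if none
exists, the best operation with a positive score (lower bound unchanged,
tau decreased); if none exists either, a fallback takes over that first
equalizes element multiplicities by inverse deletions, rescales the
ancestor's ploidies by chromosome duplications/deletions, and finishes
with content-preserving operations only -- a regime in which a
positive-score operation always exists, so termination is guaranteed.

Candidate inverse operations are generated structurally -- from
breakpoints and gray edges of the breakpoint graph, its 1-/2-bridges,
telomere scan lists, maximal duplicate segments and under-represented
segments of the ancestor -- and their exact scores are then measured by
applying each candidate and recomputing the metrics (verify-by-
recompute).  Structural generation decides only what is worth scoring,
never what a score is, so the scores are exact by construction.

The discovered inverse sequence is inverted and reversed into a forward
scenario; replaying its operations on ``rho`` reproduces ``pi`` exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterator

from .breakpoint_graph import BreakpointGraph, build as build_graph
from .genome_model import (
    Chrom,
    Genome,
    canonical_flag,
    left_ext_id,
    reflect,
    right_ext_id,
    validate_ancestor,
)
from .metrics import Metrics, RhoContext
from .operations import (
    Operation,
    OperationError,
    OpKind,
    apply,
    apply_detailed,
    invert,
)

__all__ = [
    "Score",
    "Scenario",
    "StepRecord",
    "SorterConfig",
    "sort",
    "candidate_lb_ops",
    "candidate_tau_ops",
    "fallback",
]

Score = tuple[int, int]  # (delta_lb, delta_tau), compared lexicographically


@dataclass(frozen=True)
class SorterConfig:
    """Caps and knobs of the greedy search.

    ``max_steps`` bounds each greedy phase (default ``10 * n + 100``);
    exceeding it triggers the fallback rather than failure.  The
    remaining caps bound candidate generation per family; they trade
    scenario quality against runtime and do not affect correctness
    because every emitted candidate is scored exactly.
    """

    max_steps: int | None = None
    max_candidates: int = 900
    per_gray_edge: int = 8
    max_fusion_ends: int = 14
    max_swap_sites: int = 6
    max_insert_sites: int = 2
    max_bridge_candidates: int = 120
    use_two_bridges: bool = True
    collect_trace: bool = True


@dataclass(frozen=True)
class StepRecord:
    """One accepted inverse step of the search, for tracing/benchmarks."""

    index: int
    phase: str  # "lb" | "tau" | "fallback_insert" | "fallback_ploidy" | "fallback_sort"
    inverse_kind: str
    forward_kind: str
    sigma: Score
    lb_after: int
    tau_after: int
    weight: int


@dataclass(frozen=True)
class Scenario:
    """A forward operation sequence transforming the ancestor into the
    descendant, with its total weight and the search trace."""

    operations: tuple[Operation, ...]
    total_weight: int
    trace: tuple[StepRecord, ...]
    fallback_used: bool

    def replay(self, rho: Genome) -> Genome:
        g = rho
        for op in self.operations:
            g = apply(op, g)
        return g


class SortError(RuntimeError):
    """Internal failure of the sorting loop (indicates a bug)."""


# ---------------------------------------------------------------------------
# candidate generation
#
# A candidate is an inverse operation `action` applicable to the current
# genome, plus an optional builder for the forward operation it inverts.
# When the builder is None the forward operation is `invert(action, cur)`
# (content-preserving kinds, insertions).  Duplicate removals need an
# explicit builder because a deletion of a surplus copy inverts, by
# model, to a tandem/transposition/chromosome duplication.

ForwardBuilder = Callable[[Genome, Operation], Operation]


@dataclass
class _State:
    """Per-step scan of the current genome against the ancestor context."""

    cur: Genome
    ctx: RhoContext
    mult: list[int]
    pi_tel: list[int]
    expose_R: dict[int, list[tuple[Chrom, int]]]
    expose_L: dict[int, list[tuple[Chrom, int]]]
    ends: list[tuple[Chrom, str, int]]
    bp_cuts: dict[Chrom, list[int]]
    bp_sites: dict[tuple[int, int], list[tuple[Chrom, int]]]


def _scan(ctx: RhoContext, cur: Genome) -> _State:
    gray = ctx.gray
    mult = [0] * (ctx.n + 1)
    pi_tel = [0] * (2 * ctx.n)
    expose_R: dict[int, list] = {}
    expose_L: dict[int, list] = {}
    ends: list[tuple[Chrom, str, int]] = []
    bp_cuts: dict[Chrom, list[int]] = {}
    bp_sites: dict[tuple[int, int], list] = {}
    for K, count in cur.counts.items():
        m = len(K)
        cuts = []
        for i in range(1, m):
            u = right_ext_id(K[i - 1])
            v = left_ext_id(K[i])
            pair = (u, v) if u <= v else (v, u)
            if pair not in gray:
                cuts.append(i)
                expose_R.setdefault(u, []).append((K, i))
                expose_L.setdefault(v, []).append((K, i))
                bp_sites.setdefault(pair, []).append((K, i))
        bp_cuts[K] = cuts
        lE, rE = left_ext_id(K[0]), right_ext_id(K[-1])
        ends.append((K, "L", lE))
        ends.append((K, "R", rE))
        expose_L.setdefault(lE, []).append((K, 0))
        expose_R.setdefault(rE, []).append((K, m))
        for x in K:
            mult[abs(x)] += count
        pi_tel[lE] += count
        pi_tel[rE] += count
    return _State(cur, ctx, mult, pi_tel, expose_R, expose_L, ends, bp_cuts, bp_sites)


def _dcj_cut_ops(K1: Chrom, c1: int, K2: Chrom, c2: int, counts) -> list[Operation]:
    """Named operations realizable by a DCJ cutting at ``(K1,c1), (K2,c2)``."""
    ops: list[Operation] = []
    if K1 is K2 or (K1 == K2 and counts.get(K1, 0) < 2):
        lo, hi = min(c1, c2), max(c1, c2)
        if lo < hi and not (lo == 0 and hi == len(K1)):
            ops.append(Operation(OpKind.REVERSAL, chrom=K1, start=lo, end=hi))
        return ops
    m1, m2 = len(K1), len(K2)
    # straight join: K1[:c1]+K2[c2:], K2[:c2]+K1[c1:]
    if c1 == 0 and c2 == m2:
        ops.append(Operation(OpKind.FUSION, chrom=K2, chrom_b=K1))
    elif c1 == m1 and c2 == 0:
        ops.append(Operation(OpKind.FUSION, chrom=K1, chrom_b=K2))
    else:
        ops.append(Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2, pos=c1, pos_b=c2))
    # reflected join: K1[:c1]+reflect(K2[:c2]), reflect(K1[c1:])+K2[c2:]
    if c1 == 0 and c2 == 0:
        ops.append(Operation(OpKind.FUSION, chrom=K1, chrom_b=K2, reflect_a=True))
    elif c1 == m1 and c2 == m2:
        ops.append(Operation(OpKind.FUSION, chrom=K1, chrom_b=K2, reflect_b=True))
    else:
        ops.append(
            Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2,
                      pos=c1, pos_b=m2 - c2, reflect_b=True)
        )
    return ops


def _gen_adjacency_joins(st: _State, cfg: SorterConfig) -> Iterator[tuple[Operation, None]]:
    """Content-preserving ops creating a missing ancestor adjacency while
    cutting only at breakpoints or chromosome ends."""
    counts = st.cur.counts
    for edge in sorted(st.ctx.gray):
        combos = 0
        for u, w in (edge, (edge[1], edge[0])):
            # join u (read rightwards) to w (read leftwards)
            for (K1, i) in st.expose_R.get(u, ()):
                if combos >= cfg.per_gray_edge:
                    break
                for (K2, j) in st.expose_L.get(w, ()):
                    if combos >= cfg.per_gray_edge:
                        break
                    if K1 == K2 and counts[K1] == 1:
                        # same molecule: a transposition moves a segment so
                        # that elements i-1 and j become adjacent
                        if i < j:
                            base_len = len(K1) - (j - i)
                            cand = {0, base_len}
                            for k in st.bp_cuts[K1]:
                                if k <= i:
                                    cand.add(k)
                                elif k >= j:
                                    cand.add(k - (j - i))
                            cand.discard(i)
                            for p in sorted(cand)[:3]:
                                yield Operation(OpKind.TRANSPOSITION, chrom=K1,
                                                start=i, end=j, insert=p), None
                                combos += 1
                        elif j < i:
                            ks = [k for k in st.bp_cuts[K1] if j < k < i]
                            if ks:
                                k = ks[0]
                                yield Operation(OpKind.TRANSPOSITION, chrom=K1,
                                                start=j, end=k, insert=i - (k - j)), None
                                combos += 1
                    else:
                        if i == 0 and j == 0:
                            continue
                        if i == len(K1) and j == 0:
                            yield Operation(OpKind.FUSION, chrom=K1, chrom_b=K2), None
                        elif j == 0 and i < len(K1):
                            # joining u to the start of K2 keeps both pieces
                            yield Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2,
                                            pos=i, pos_b=0), None
                        else:
                            yield Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2,
                                            pos=i, pos_b=j), None
                        combos += 1
        # same-orientation pairs: u and w both read rightwards / leftwards
        u, w = edge
        for (K1, i), (K2, j) in itertools.islice(
            itertools.product(st.expose_R.get(u, ()), st.expose_R.get(w, ())),
            3 * cfg.per_gray_edge,
        ):
            if K1 == K2 and counts[K1] == 1:
                if i < j:
                    yield Operation(OpKind.REVERSAL, chrom=K1, start=i, end=j), None
            elif i == len(K1) and j == len(K2):
                yield Operation(OpKind.FUSION, chrom=K1, chrom_b=K2, reflect_b=True), None
            else:
                yield Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2,
                                pos=i, pos_b=len(K2) - j, reflect_b=True), None
        for (K1, i), (K2, j) in itertools.islice(
            itertools.product(st.expose_L.get(u, ()), st.expose_L.get(w, ())),
            3 * cfg.per_gray_edge,
        ):
            if K1 == K2 and counts[K1] == 1:
                if i < j and not (i == 0 and j == len(K1)):
                    yield Operation(OpKind.REVERSAL, chrom=K1, start=i, end=j), None
            else:
                if i == 0 and j == 0:
                    yield Operation(OpKind.FUSION, chrom=K1, chrom_b=K2, reflect_a=True), None
                else:
                    yield Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2,
                                    pos=len(K1) - i, pos_b=j, reflect_a=True), None


def _gen_fissions(st: _State) -> Iterator[tuple[Operation, None]]:
    for K, cuts in st.bp_cuts.items():
        for i in cuts:
            yield Operation(OpKind.FISSION, chrom=K, pos=i), None


def _gen_surplus_fusions(st: _State, cfg: SorterConfig) -> Iterator[tuple[Operation, None]]:
    """Fusions consuming two telomeres that the ancestor does not have."""
    rho_tel = st.ctx.rho_tel
    surplus = [e for e in st.ends if rho_tel[e[2]] == 0][: cfg.max_fusion_ends]
    counts = st.cur.counts
    for (K1, s1, _), (K2, s2, _) in itertools.combinations(surplus, 2):
        if K1 == K2 and counts[K1] < 2:
            continue  # both ends of a single copy: fusing would circularize
        if s1 == "R" and s2 == "L":
            yield Operation(OpKind.FUSION, chrom=K1, chrom_b=K2), None
        elif s1 == "L" and s2 == "R":
            yield Operation(OpKind.FUSION, chrom=K2, chrom_b=K1), None
        elif s1 == "R" and s2 == "R":
            yield Operation(OpKind.FUSION, chrom=K1, chrom_b=K2, reflect_b=True), None
        else:
            yield Operation(OpKind.FUSION, chrom=K1, chrom_b=K2, reflect_a=True), None


def _gen_telomere_swaps(st: _State, cfg: SorterConfig) -> Iterator[tuple[Operation, None]]:
    """DCJs that trade a surplus telomere for a missing ancestor telomere."""
    rho_tel = st.ctx.rho_tel
    counts = st.cur.counts
    surplus = [e for e in st.ends if rho_tel[e[2]] == 0][: cfg.max_swap_sites]
    deficits = [v for v in range(2 * st.ctx.n) if rho_tel[v] > st.pi_tel[v]]
    for K1, side, _u in surplus:
        m1 = len(K1)
        for v in deficits:
            vR = [(K, c) for (K, c) in st.expose_R.get(v, ()) if 1 <= c <= len(K) - 1]
            vL = [(K, c) for (K, c) in st.expose_L.get(v, ()) if 1 <= c <= len(K) - 1]
            for K2, j in vR[: cfg.max_swap_sites]:
                if K1 == K2 and counts[K1] == 1:
                    if side == "L":
                        yield Operation(OpKind.REVERSAL, chrom=K1, start=0, end=j), None
                elif side == "R":
                    yield Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2,
                                    pos=m1, pos_b=j), None
                else:
                    yield Operation(OpKind.TRANSLOCATION, chrom=K2, chrom_b=K1,
                                    pos=len(K2) - j, pos_b=0, reflect_a=True), None
            for K2, j in vL[: cfg.max_swap_sites]:
                if K1 == K2 and counts[K1] == 1:
                    if side == "R":
                        yield Operation(OpKind.REVERSAL, chrom=K1, start=j, end=m1), None
                elif side == "R":
                    yield Operation(OpKind.TRANSLOCATION, chrom=K1, chrom_b=K2,
                                    pos=m1, pos_b=len(K2) - j, reflect_b=True), None
                else:
                    yield Operation(OpKind.TRANSLOCATION, chrom=K2, chrom_b=K1,
                                    pos=j, pos_b=0), None


# -- duplicate removals (inverse duplications) ------------------------------

def _forward_tandem(cur: Genome, action: Operation) -> Operation:
    _, info = apply_detailed(action, cur)
    r = info.results[0]
    L = action.end - action.start
    lo = action.start - L
    if r.reflected:
        s, e = len(r.raw) - action.start, len(r.raw) - lo
    else:
        s, e = lo, action.start
    return Operation(OpKind.TANDEM_DUPLICATION, chrom=r.canon, start=s, end=e)


def _forward_chrom_dup(cur: Genome, action: Operation) -> Operation:
    return Operation(OpKind.CHROMOSOME_DUPLICATION, chrom=action.chrom)


def _make_forward_transposition_dup(src: Chrom | None, s2: int, L: int,
                                    other_strand: bool) -> ForwardBuilder:
    def build(cur: Genome, action: Operation) -> Operation:
        _, info = apply_detailed(action, cur)
        r = info.results[0]
        d = action.start
        ins = len(r.raw) - d if r.reflected else d
        src_key = r.canon if src is None else src
        return Operation(
            OpKind.TRANSPOSITION_DUPLICATION, chrom=src_key,
            start=s2, end=s2 + L, chrom_b=r.canon, insert=ins,
            reflect_a=other_strand,
        )

    return build


def _tandem_repeats(K: Chrom, limit: int = 8) -> list[tuple[int, int]]:
    """Positions ``(j, L)`` with ``K[j-L:j] == K[j:j+L]``, maximal ``L``
    preferred, longest first."""
    m = len(K)
    found: list[tuple[int, int]] = []
    for j in range(1, m):
        best = 0
        for L in range(1, min(j, m - j) + 1):
            if K[j - L] == K[j] and K[j - 1] == K[j + L - 1] and K[j - L : j] == K[j : j + L]:
                best = L
        if best:
            found.append((j, best))
    found.sort(key=lambda t: (-t[1], t[0]))
    return found[:limit]


def _gen_duplicate_removals(st: _State, cfg: SorterConfig) -> Iterator[tuple[Operation, ForwardBuilder]]:
    counts = st.cur.counts
    rho_mult = st.ctx.rho_mult
    # identical chromosome copies
    for K, c in counts.items():
        if c >= 2:
            yield Operation(OpKind.CHROMOSOME_DELETION, chrom=K), _forward_chrom_dup
    for K in counts:
        m = len(K)
        surplus = [rho_mult[abs(x)] < st.mult[abs(x)] for x in K]
        # adjacent identical copies -> inverse tandem duplication
        for j, L in _tandem_repeats(K):
            if any(surplus[j : j + L]) or any(surplus[j - L : j]):
                yield (
                    Operation(OpKind.DELETION, chrom=K, start=j, end=j + L),
                    _forward_tandem,
                )
        # surplus runs with an identical copy elsewhere -> inverse
        # transposition duplication; long runs are decomposed greedily
        # into the longest chunks that still have a copy
        runs = []
        i = 0
        while i < m:
            if surplus[i]:
                j = i
                while j < m and surplus[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        for a, b in runs:
            for s, e in _copy_chunks(st, K, a, b):
                if e - s == m:
                    continue
                builder = _match_remaining_copy(st, K, s, e)
                if builder is not None:
                    yield Operation(OpKind.DELETION, chrom=K, start=s, end=e), builder


def _copy_chunks(st: _State, K: Chrom, a: int, b: int, cap: int = 4) -> list[tuple[int, int]]:
    """Greedy decomposition of the surplus run ``K[a:b)`` into chunks that
    occur (in some orientation) elsewhere in the genome: seed on each
    element occurrence, extend as far as the copies agree, take the
    longest extension, continue after it."""
    chunks: list[tuple[int, int]] = []
    s = a
    while s < b and len(chunks) < cap:
        best_f = best_r = 0
        x = K[s]
        for K2, c2 in st.cur.counts.items():
            m2 = len(K2)
            for q in range(m2):
                if K2 is K and c2 == 1 and q == s:
                    continue
                if K2[q] == x:  # same-orientation copy
                    L = 1
                    while s + L < b and q + L < m2 and K2[q + L] == K[s + L]:
                        L += 1
                    if L > best_f:
                        best_f = L
                elif K2[q] == -x:  # reflected copy
                    L = 1
                    while s + L < b and q - L >= 0 and K2[q - L] == -K[s + L]:
                        L += 1
                    if L > best_r:
                        best_r = L
        best = max(best_f, best_r)
        if best:
            # propose both orientations' extents; whether a proposal is a
            # legal inverse duplication is settled by the copy matcher
            chunks.append((s, s + best))
            s += best
        else:
            s += 1
    return chunks


def _match_remaining_copy(st: _State, K: Chrom, s: int, e: int) -> ForwardBuilder | None:
    """Locate, in the genome after removing ``K[s:e)``, an identical copy of
    the removed segment in the orientation the forward transposition
    duplication needs; None when no such copy exists.  The source may be
    read from either strand (chromosomes equal their reflections), so a
    reflected occurrence serves as well."""
    seg = K[s:e]
    L = e - s
    rest_canon, refl = canonical_flag(K[:s] + K[e:])
    needed = reflect(seg) if refl else seg
    needed_r = reflect(needed)
    for K2, c in st.cur.counts.items():
        if K2 == K:
            haystacks = [rest_canon] if c == 1 else [rest_canon, K2]
        else:
            haystacks = [K2]
        for hay in haystacks:
            src = None if hay is rest_canon else hay
            for off in range(len(hay) - L + 1):
                piece = hay[off : off + L]
                if piece == needed:
                    return _make_forward_transposition_dup(src, off, L, False)
                if piece == needed_r:
                    # reflect(hay)[m-off-L : m-off] == needed
                    return _make_forward_transposition_dup(
                        src, len(hay) - off - L, L, True
                    )
    return None


# -- insertions (inverse deletions) -----------------------------------------

def _gen_insertions(st: _State, cfg: SorterConfig) -> Iterator[tuple[Operation, None]]:
    """Insert maximal runs of under-represented ancestor segments, next to
    an existing occurrence of a neighbouring element so that at least one
    new junction is an ancestor adjacency; whole missing chromosomes are
    inserted as new chromosomes."""
    rho_mult = st.ctx.rho_mult
    deficit = [rho_mult[x] - st.mult[x] for x in range(st.ctx.n + 1)]
    if not any(d > 0 for d in deficit):
        return
    for R in st.ctx.rho.counts:
        m = len(R)
        i = 0
        while i < m:
            if deficit[abs(R[i])] <= 0:
                i += 1
                continue
            j = i
            while j < m and deficit[abs(R[j])] > 0:
                j += 1
            seg = R[i:j]
            if i == 0 and j == m:
                yield Operation(OpKind.CHROMOSOME_INSERTION, segment=R), None
            else:
                emitted = 0
                if i > 0:
                    prev = R[i - 1]
                    for K, q, fwd in _occurrences(st, prev, cfg.max_insert_sites):
                        if fwd:
                            yield Operation(OpKind.INSERTION, chrom=K, pos=q + 1, segment=seg), None
                        else:
                            yield Operation(OpKind.INSERTION, chrom=K, pos=q, segment=reflect(seg)), None
                        emitted += 1
                if j < m:
                    nxt = R[j]
                    for K, q, fwd in _occurrences(st, nxt, cfg.max_insert_sites):
                        if fwd:
                            yield Operation(OpKind.INSERTION, chrom=K, pos=q, segment=seg), None
                        else:
                            yield Operation(OpKind.INSERTION, chrom=K, pos=q + 1, segment=reflect(seg)), None
                        emitted += 1
                if not emitted:
                    yield Operation(OpKind.CHROMOSOME_INSERTION, segment=seg), None
            i = j


def _occurrences(st: _State, signed: int, cap: int):
    """Up to ``cap`` occurrences of a signed element: (chrom, index, same_orientation)."""
    out = []
    for K in st.cur.counts:
        for q, x in enumerate(K):
            if x == signed:
                out.append((K, q, True))
            elif x == -signed:
                out.append((K, q, False))
            if len(out) >= cap:
                return out
    return out


# -- bridge-driven DCJs ------------------------------------------------------

def _gen_bridge_ops(st: _State, cfg: SorterConfig, bg: BreakpointGraph) -> Iterator[tuple[Operation, None]]:
    counts = st.cur.counts
    emitted = 0
    end_cuts: list[tuple[Chrom, int]] = []
    for K in counts:
        end_cuts.append((K, 0))
        end_cuts.append((K, len(K)))
    ones = bg.one_bridge_edges()
    for e in ones:
        for K1, c1 in st.bp_sites.get(e, ())[:2]:
            partners = end_cuts + [
                site for cuts in (st.bp_sites.get(f, ())[:1] for f in ones if f != e)
                for site in cuts
            ]
            for K2, c2 in partners:
                for op in _dcj_cut_ops(K1, c1, K2, c2, counts):
                    yield op, None
                    emitted += 1
                    if emitted >= cfg.max_bridge_candidates:
                        return
    if cfg.use_two_bridges:
        for e1, e2 in bg.two_bridge_edges():
            sites1 = st.bp_sites.get(e1, ())
            sites2 = st.bp_sites.get(e2, ())
            for (K1, c1), (K2, c2) in itertools.islice(itertools.product(sites1, sites2), 4):
                if (K1, c1) == (K2, c2):
                    continue
                for op in _dcj_cut_ops(K1, c1, K2, c2, counts):
                    yield op, None
                    emitted += 1
                    if emitted >= cfg.max_bridge_candidates:
                        return


def _gen_rescue(st: _State, cfg: SorterConfig) -> Iterator[tuple[Operation, None]]:
    """Exhaustive DCJs over all breakpoint cuts and chromosome ends; the
    safety net of the content-preserving phase."""
    counts = st.cur.counts
    all_cuts: list[tuple[Chrom, int]] = []
    for K, cuts in st.bp_cuts.items():
        all_cuts.extend((K, c) for c in cuts)
        all_cuts.append((K, 0))
        all_cuts.append((K, len(K)))
    for (K1, c1), (K2, c2) in itertools.combinations(all_cuts, 2):
        for op in _dcj_cut_ops(K1, c1, K2, c2, counts):
            yield op, None


# ---------------------------------------------------------------------------
# scoring and the greedy loop

@dataclass(frozen=True)
class Candidate:
    action: Operation
    score: Score
    next_genome: Genome
    next_metrics: Metrics
    forward_builder: ForwardBuilder | None

    def forward(self, cur: Genome) -> Operation:
        if self.forward_builder is not None:
            return self.forward_builder(cur, self.action)
        return invert(self.action, cur)


def _evaluate(
    ctx: RhoContext,
    cur: Genome,
    cur_m: Metrics,
    moves,
    cfg: SorterConfig,
) -> list[Candidate]:
    seen: set = set()
    out: list[Candidate] = []
    for action, builder in moves:
        key = (action.kind, action.sort_key())
        if key in seen:
            continue
        seen.add(key)
        if len(out) >= cfg.max_candidates:
            break
        try:
            nxt = apply(action, cur)
        except OperationError:
            continue
        mets = ctx.evaluate(nxt.chromosomes)
        score = (cur_m.lb - mets.lb, cur_m.tau - mets.tau)
        out.append(Candidate(action, score, nxt, mets, builder))
    return out


def _moves(st: _State, cfg: SorterConfig, content_ops: bool, bg: BreakpointGraph | None):
    if content_ops:
        yield from _gen_duplicate_removals(st, cfg)
        yield from _gen_insertions(st, cfg)
    yield from _gen_fissions(st)
    yield from _gen_surplus_fusions(st, cfg)
    yield from _gen_telomere_swaps(st, cfg)
    yield from _gen_adjacency_joins(st, cfg)
    if bg is not None:
        yield from _gen_bridge_ops(st, cfg, bg)


def _best(cands: list[Candidate], accept) -> Candidate | None:
    best: Candidate | None = None
    for c in cands:
        if not accept(c.score):
            continue
        if best is None or c.score > best.score or (
            c.score == best.score and c.action.sort_key() < best.action.sort_key()
        ):
            best = c
    return best


class _Greedy:
    """Greedy loop toward a fixed target genome."""

    def __init__(self, target: Genome, cfg: SorterConfig, content_ops: bool = True):
        self.target = target
        self.ctx = RhoContext(target, n=target.n)
        self.cfg = cfg
        self.content_ops = content_ops

    def run(self, start: Genome, phase: str, steps_out: list, trace: list,
            budget: int | None = None) -> Genome:
        """Advance from ``start`` until the target is reached or no
        positive-score candidate remains; returns the final genome."""
        cfg = self.cfg
        cur = start
        max_steps = budget if budget is not None else cfg.max_steps or (10 * self.ctx.n + 100)
        for _ in range(max_steps):
            if cur.chromosomes == self.target.chromosomes:
                return cur
            cur_m = self.ctx.evaluate(cur.chromosomes)
            st = _scan(self.ctx, cur)
            cands = _evaluate(self.ctx, cur, cur_m, _moves(st, cfg, self.content_ops, None), cfg)
            chosen = _best(cands, lambda s: s[0] >= 1)
            used_phase = phase + ":lb" if phase == "main" else phase
            if chosen is None:
                # bridge-driven candidates are only generated on demand
                bg = BreakpointGraph(self.ctx.n, self.ctx.gray, _black(self.ctx, cur))
                extra = _evaluate(self.ctx, cur, cur_m,
                                  _gen_bridge_ops(st, cfg, bg), cfg)
                chosen = _best(cands + extra, lambda s: s[0] >= 1)
            if chosen is None:
                chosen = _best(cands, lambda s: s[0] >= 0 and s > (0, 0))
                used_phase = phase + ":tau" if phase == "main" else phase
            if chosen is None and not self.content_ops:
                rescue = _evaluate(self.ctx, cur, cur_m, _gen_rescue(st, cfg), cfg)
                chosen = _best(rescue, lambda s: s[0] >= 0 and s > (0, 0))
            if chosen is None:
                return cur
            forward = chosen.forward(cur)
            steps_out.append(forward)
            if cfg.collect_trace:
                trace.append(StepRecord(
                    index=len(trace), phase=used_phase,
                    inverse_kind=chosen.action.kind.value,
                    forward_kind=forward.kind.value,
                    sigma=chosen.score,
                    lb_after=chosen.next_metrics.lb,
                    tau_after=chosen.next_metrics.tau,
                    weight=forward.weight,
                ))
            cur = chosen.next_genome
        return cur


def _black(ctx: RhoContext, cur: Genome):
    from collections import Counter

    from .genome_model import junction_ids

    black: Counter = Counter()
    covered = ctx.gray_covered
    for ch in cur.chromosomes:
        for u, v in junction_ids(ch):
            if covered[u] and covered[v]:
                black[(u, v)] += 1
    return black


# ---------------------------------------------------------------------------
# fallback

def _fallback_insertions(ctx: RhoContext, cur: Genome, steps, trace, cfg) -> Genome:
    """Phase (a): per ancestor chromosome, raise every element whose
    multiplicity trails the chromosome's maximum by inserting maximal
    ancestor segments (inverse deletions)."""
    while True:
        mult = [0] * (ctx.n + 1)
        for ch in cur.chromosomes:
            for x in ch:
                mult[abs(x)] += 1
        action = None
        for R in sorted(ctx.rho.counts):
            M = max(mult[abs(z)] for z in R)
            if M == 0:
                continue
            m = len(R)
            i = 0
            while i < m:
                if mult[abs(R[i])] >= M:
                    i += 1
                    continue
                j = i
                while j < m and mult[abs(R[j])] < M:
                    j += 1
                seg = R[i:j]
                if i == 0 and j == m:
                    action = Operation(OpKind.CHROMOSOME_INSERTION, segment=R)
                elif i > 0:
                    K, q, fwd = _first_occurrence(cur, R[i - 1])
                    action = (
                        Operation(OpKind.INSERTION, chrom=K, pos=q + 1, segment=seg)
                        if fwd else
                        Operation(OpKind.INSERTION, chrom=K, pos=q, segment=reflect(seg))
                    )
                else:
                    K, q, fwd = _first_occurrence(cur, R[j])
                    action = (
                        Operation(OpKind.INSERTION, chrom=K, pos=q, segment=seg)
                        if fwd else
                        Operation(OpKind.INSERTION, chrom=K, pos=q + 1, segment=reflect(seg))
                    )
                break
            if action is not None:
                break
        if action is None:
            return cur
        forward = invert(action, cur)
        steps.append(forward)
        nxt = apply(action, cur)
        if cfg.collect_trace:
            mets = ctx.evaluate(nxt.chromosomes)
            trace.append(StepRecord(
                index=len(trace), phase="fallback_insert",
                inverse_kind=action.kind.value, forward_kind=forward.kind.value,
                sigma=(0, 0), lb_after=mets.lb, tau_after=mets.tau,
                weight=forward.weight,
            ))
        cur = nxt


def _first_occurrence(cur: Genome, signed: int):
    for K in cur.counts:
        for q, x in enumerate(K):
            if x == signed:
                return K, q, True
            if x == -signed:
                return K, q, False
    raise SortError(f"fallback: no occurrence of element {signed}")


def fallback(rho: Genome, pi: Genome, config: SorterConfig | None = None) -> Scenario:
    """The guaranteed-terminating completion from a stuck state.

    Equalizes multiplicities by inverse deletions, rescales the ancestor's
    chromosome copy numbers to match, sorts with content-preserving
    operations only (a positive-score operation always exists in that
    regime), and accounts for the ploidy rescaling as forward chromosome
    duplications/deletions at the start of the scenario.
    """
    cfg = config or SorterConfig()
    n = max(rho.n, pi.n)
    rho = Genome(rho.chromosomes, n=n)
    pi = Genome(pi.chromosomes, n=n)
    ctx = RhoContext(rho, n=n)
    steps: list[Operation] = []
    trace: list[StepRecord] = []
    cur = _fallback_insertions(ctx, pi, steps, trace, cfg)

    # phase (b): rescale rho's ploidies to match cur's multiplicities
    mult = [0] * (n + 1)
    for ch in cur.chromosomes:
        for x in ch:
            mult[abs(x)] += 1
    pre_ops: list[Operation] = []
    prime: list[Chrom] = []
    for K, c in sorted(rho.counts.items()):
        want = mult[abs(K[0])]
        prime.extend([K] * want)
        if want > c:
            pre_ops.extend([Operation(OpKind.CHROMOSOME_DUPLICATION, chrom=K)] * (want - c))
        elif want < c:
            pre_ops.extend([Operation(OpKind.CHROMOSOME_DELETION, chrom=K)] * (c - want))
    if not prime:
        raise SortError("fallback: descendant shares no content with the ancestor")
    rho_prime = Genome(prime, n=n)
    for op in pre_ops:
        if cfg.collect_trace:
            trace.append(StepRecord(
                index=len(trace), phase="fallback_ploidy",
                inverse_kind="-", forward_kind=op.kind.value,
                sigma=(0, 0), lb_after=-1, tau_after=-1, weight=op.weight,
            ))

    # phase (c): content-preserving sort toward rho'; every step strictly
    # lowers the (lb, tau) potential, so a budget derived from the initial
    # potential is a pure safety net, not a tuning knob
    loop = _Greedy(rho_prime, cfg, content_ops=False)
    start_m = loop.ctx.evaluate(cur.chromosomes)
    budget = 10 * n + 1000 + start_m.tau + start_m.lb
    cur = loop.run(cur, "fallback_sort", steps, trace, budget=budget)
    if cur.chromosomes != rho_prime.chromosomes:
        raise SortError(
            "fallback failed to finish with content-preserving operations; "
            "this violates the guaranteed-progress property and is a bug"
        )
    ops = tuple(pre_ops) + tuple(reversed(steps))
    return Scenario(
        operations=ops,
        total_weight=sum(op.weight for op in ops),
        trace=tuple(trace),
        fallback_used=True,
    )


# ---------------------------------------------------------------------------
# public API

def sort(rho: Genome, pi: Genome, config: SorterConfig | None = None) -> Scenario:
    """Find a forward scenario transforming ``rho`` into ``pi``.

    The ancestor must satisfy the disjoint-or-identical constraint.  The
    returned scenario replays exactly: ``scenario.replay(rho) == pi``.
    """
    validate_ancestor(rho).raise_for_violations()
    cfg = config or SorterConfig()
    n = max(rho.n, pi.n)
    rho_n = Genome(rho.chromosomes, n=n)
    pi_n = Genome(pi.chromosomes, n=n)
    steps: list[Operation] = []
    trace: list[StepRecord] = []
    loop = _Greedy(rho_n, cfg, content_ops=True)
    cur = loop.run(pi_n, "main", steps, trace)
    if cur.chromosomes == rho_n.chromosomes:
        ops = tuple(reversed(steps))
        return Scenario(ops, sum(op.weight for op in ops), tuple(trace), False)
    tail = fallback(rho_n, cur, cfg)
    ops = tail.operations + tuple(reversed(steps))
    return Scenario(
        operations=ops,
        total_weight=sum(op.weight for op in ops),
        trace=tuple(trace) + tail.trace,
        fallback_used=True,
    )


def candidate_lb_ops(
    rho: Genome, pi: Genome, bg: BreakpointGraph | None = None,
    config: SorterConfig | None = None,
) -> list[tuple[Operation, Score]]:
    """Inverse operations that decrease the lower bound, with their scores."""
    cfg = config or SorterConfig()
    n = max(rho.n, pi.n)
    ctx = RhoContext(Genome(rho.chromosomes, n=n), n=n)
    cur = Genome(pi.chromosomes, n=n)
    cur_m = ctx.evaluate(cur.chromosomes)
    st = _scan(ctx, cur)
    if bg is None:
        bg = build_graph(rho, pi)
    cands = _evaluate(ctx, cur, cur_m, _moves(st, cfg, True, bg), cfg)
    return sorted(
        [(c.action, c.score) for c in cands if c.score[0] >= 1],
        key=lambda t: (tuple(-x for x in t[1]), t[0].sort_key()),
    )


def candidate_tau_ops(
    rho: Genome, pi: Genome, config: SorterConfig | None = None,
) -> list[tuple[Operation, Score]]:
    """Inverse operations with positive score that keep the lower bound."""
    cfg = config or SorterConfig()
    n = max(rho.n, pi.n)
    ctx = RhoContext(Genome(rho.chromosomes, n=n), n=n)
    cur = Genome(pi.chromosomes, n=n)
    cur_m = ctx.evaluate(cur.chromosomes)
    st = _scan(ctx, cur)
    cands = _evaluate(ctx, cur, cur_m, _moves(st, cfg, True, None), cfg)
    return sorted(
        [(c.action, c.score) for c in cands if c.score[0] == 0 and c.score > (0, 0)],
        key=lambda t: (tuple(-x for x in t[1]), t[0].sort_key()),
    )
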