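"""Exact minimum-weight distances on tiny instances.

A bidirectional uniform-cost search meets in the middle: one frontier
expands forward from the ancestor using every parameterization of the
eleven operation kinds, the other expands backward from the descendant
using every inverse operation.  Inverse deletions (insertions) are
restricted to contiguous ancestor substrings -- the same restriction the
greedy sorter obeys -- so the value returned is the exact optimum of that
restricted model and an upper bound on the unrestricted optimum; it is
still bounded below by the lower bound, which makes it the reference for
sandwich checks ``lb <= d <= sorter weight``.

Only desk-toy sizes are feasible: the search radius is half the weight
limit per side, so the default limit of 4 expands each frontier to
weight 2.
"""

from __future__ import annotations

from typing import Iterator

from .genome_model import Chrom, Genome, canonical_flag, reflect
from .operations import Operation, OperationError, OpKind, apply

__all__ = ["exact_distance", "forward_operations", "inverse_operations"]


def _all_segments(K: Chrom):
    m = len(K)
    for s in range(m):
        for e in range(s + 1, m + 1):
            yield s, e


def forward_operations(g: Genome) -> Iterator[Operation]:
    """Every parameterization of the eleven forward kinds on ``g``."""
    keys = sorted(g.counts)
    total = len(g.chromosomes)
    for K in keys:
        m = len(K)
        for s, e in _all_segments(K):
            yield Operation(OpKind.REVERSAL, chrom=K, start=s, end=e)
            yield Operation(OpKind.TANDEM_DUPLICATION, chrom=K, start=s, end=e)
            if not (s == 0 and e == m and total == 1):
                yield Operation(OpKind.DELETION, chrom=K, start=s, end=e)
            if e - s < m:
                for ins in range(m - (e - s) + 1):
                    if ins != s:
                        yield Operation(OpKind.TRANSPOSITION, chrom=K, start=s, end=e, insert=ins)
                    yield Operation(OpKind.INVERTED_TRANSPOSITION, chrom=K, start=s, end=e, insert=ins)
            for Kd in keys:
                for ins in range(len(Kd) + 1):
                    yield Operation(OpKind.TRANSPOSITION_DUPLICATION, chrom=K, start=s, end=e,
                                    chrom_b=Kd, insert=ins)
        for pos in range(1, m):
            yield Operation(OpKind.FISSION, chrom=K, pos=pos)
        yield Operation(OpKind.CHROMOSOME_DUPLICATION, chrom=K)
        if total >= 2:
            yield Operation(OpKind.CHROMOSOME_DELETION, chrom=K)
    for i, Ka in enumerate(keys):
        for Kb in keys[i:]:
            if Ka == Kb and g.counts[Ka] < 2:
                continue
            for ra in (False, True):
                for rb in (False, True):
                    yield Operation(OpKind.FUSION, chrom=Ka, chrom_b=Kb, reflect_a=ra, reflect_b=rb)
                    for pa in range(len(Ka) + 1):
                        for pb in range(len(Kb) + 1):
                            yield Operation(OpKind.TRANSLOCATION, chrom=Ka, chrom_b=Kb,
                                            pos=pa, pos_b=pb, reflect_a=ra, reflect_b=rb)


def _rho_substrings(rho: Genome) -> list[Chrom]:
    segs = set()
    for K in rho.counts:
        for s, e in _all_segments(K):
            segs.add(K[s:e])
            segs.add(reflect(K[s:e]))
    return sorted(segs)


def _has_remaining_copy(g: Genome, K: Chrom, s: int, e: int) -> bool:
    """True when removing ``K[s:e)`` is a valid inverse transposition
    duplication: the segment survives elsewhere, on either strand."""
    seg = K[s:e]
    L = e - s
    rest_canon, refl = canonical_flag(K[:s] + K[e:])
    needed = reflect(seg) if refl else seg
    needed_r = reflect(needed)
    for K2, c in g.counts.items():
        if K2 == K:
            haystacks = [rest_canon] if c == 1 else [rest_canon, K2]
        else:
            haystacks = [K2]
        for hay in haystacks:
            for off in range(len(hay) - L + 1):
                piece = hay[off : off + L]
                if piece == needed or piece == needed_r:
                    return True
    return False


def inverse_operations(g: Genome, rho: Genome) -> Iterator[tuple[Operation, int]]:
    """Every inverse operation on ``g``, with the weight of the forward
    operation it undoes."""
    keys = sorted(g.counts)
    total = len(g.chromosomes)
    for K in keys:
        m = len(K)
        for s, e in _all_segments(K):
            yield Operation(OpKind.REVERSAL, chrom=K, start=s, end=e), 1
            if e - s < m:
                for ins in range(m - (e - s) + 1):
                    if ins != s:
                        yield Operation(OpKind.TRANSPOSITION, chrom=K, start=s, end=e, insert=ins), 2
                    yield Operation(OpKind.INVERTED_TRANSPOSITION, chrom=K, start=s, end=e, insert=ins), 2
            # deletions must undo a duplication
            L = e - s
            if s >= L and K[s - L : s] == K[s:e]:
                yield Operation(OpKind.DELETION, chrom=K, start=s, end=e), 1
            elif e - s < m and _has_remaining_copy(g, K, s, e):
                yield Operation(OpKind.DELETION, chrom=K, start=s, end=e), 2
        for pos in range(1, m):
            yield Operation(OpKind.FISSION, chrom=K, pos=pos), 1
        if g.counts[K] >= 2:
            yield Operation(OpKind.CHROMOSOME_DELETION, chrom=K), 1
    for i, Ka in enumerate(keys):
        for Kb in keys[i:]:
            if Ka == Kb and g.counts[Ka] < 2:
                continue
            for ra in (False, True):
                for rb in (False, True):
                    yield Operation(OpKind.FUSION, chrom=Ka, chrom_b=Kb, reflect_a=ra, reflect_b=rb), 1
                    for pa in range(len(Ka) + 1):
                        for pb in range(len(Kb) + 1):
                            yield Operation(OpKind.TRANSLOCATION, chrom=Ka, chrom_b=Kb,
                                            pos=pa, pos_b=pb, reflect_a=ra, reflect_b=rb), 1
    # inverse deletions: insert any ancestor substring anywhere
    for seg in _rho_substrings(rho):
        yield Operation(OpKind.CHROMOSOME_INSERTION, segment=seg), 1
        for K in keys:
            for pos in range(len(K) + 1):
                yield Operation(OpKind.INSERTION, chrom=K, pos=pos, segment=seg), 1


def _expand(dist: dict, radius: int, neighbors) -> None:
    for d in range(radius):
        for state in [s for s, ds in dist.items() if ds == d]:
            for new_state, w in neighbors(state):
                nd = d + w
                if nd <= radius and (new_state not in dist or dist[new_state] > nd):
                    dist[new_state] = nd


def exact_distance(rho: Genome, pi: Genome, max_weight: int = 4) -> int | None:
    """Exact restricted-model distance, or None if above ``max_weight``."""
    n = max(rho.n, pi.n)
    rho = Genome(rho.chromosomes, n=n)
    pi = Genome(pi.chromosomes, n=n)
    if rho.chromosomes == pi.chromosomes:
        return 0
    r_fwd = (max_weight + 1) // 2
    r_bwd = max_weight - r_fwd

    def fwd_neighbors(chroms):
        g = Genome(chroms, n=n)
        for op in forward_operations(g):
            try:
                yield apply(op, g).chromosomes, op.weight
            except OperationError:
                continue

    def bwd_neighbors(chroms):
        g = Genome(chroms, n=n)
        for op, w in inverse_operations(g, rho):
            try:
                yield apply(op, g).chromosomes, w
            except OperationError:
                continue

    dist_f: dict = {rho.chromosomes: 0}
    dist_b: dict = {pi.chromosomes: 0}
    _expand(dist_f, r_fwd, fwd_neighbors)
    _expand(dist_b, max(r_bwd, r_fwd), bwd_neighbors)
    best = None
    for state, db in dist_b.items():
        df = dist_f.get(state)
        if df is not None and (best is None or df + db < best):
            best = df + db
    if best is not None and best <= max_weight:
        return best
    return None
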