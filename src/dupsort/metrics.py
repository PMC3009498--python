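"""Quantitative machinery: incorrect telomeres, the lower bound, and tau.

For an ancestor ``rho`` (chromosomes pairwise disjoint or identical) and a
descendant ``pi`` the module computes, in pure integer arithmetic:

``T(rho, pi)`` -- incorrect telomeres: for every extremity ``e``, the
deficit ``max(0, t(rho,e) - t(pi,e))`` of ancestor telomeres missing from
``pi``, plus every telomere of ``pi`` at an extremity that is never a
telomere of ``rho``.

``lb(rho, pi)`` -- a lower bound on the weighted operation distance:

    lb = ceil(T / 2) + CL,   CL = c(rho) - C + sum_i ceil(L_i / 2)

where ``C`` is the component count of the breakpoint graph, ``L_i`` the
number of loop-carrying vertices in component ``i``, and ``c(rho)`` the
component count of the graph of ``rho`` against itself (for a valid
ancestor, ``n`` plus the number of distinct chromosomes).  No single
operation can decrease ``T`` by more than 2 nor ``CL`` by more than 1,
and an operation decreasing ``T`` leaves ``CL`` alone, hence the bound.

``tau(rho, pi)`` -- an auxiliary distance that is zero exactly at
``pi == rho`` and positive otherwise, used to rank operations that do not
move the lower bound:

    tau = m + [2*ia(rho,rho) + ta(rho,rho)] - [2*ia + ta]

with ``m = 4 * sum_x |mult(rho,x) - mult(pi,x)|``, ``ia`` the number of
inner adjacencies of ``pi`` (counted per occurrence), and ``ta`` the
number of telomere adjacencies, capped per extremity at the ancestor's
telomere count ``t(rho, e)`` so that surplus identical telomeres do not
score.  Each extremity occurrence can contribute at most 1 to
``2*ia + ta``, which makes every surplus copy of an element pay at least
2 (its ``m`` share of 4 minus at most 2 of adjacency gain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import UnionFind
from .breakpoint_graph import gray_edges_of
from .genome_model import Chrom, Genome, multiplicity_table, telomere_table

__all__ = ["Metrics", "RhoContext", "incorrect_telomeres", "lower_bound", "tau", "tau_parts", "genome_metrics"]


@dataclass(frozen=True)
class Metrics:
    """All per-pair quantities, recomputable from the two genomes alone."""

    T: int
    C: int
    L: int
    L_per_component: tuple[int, ...]
    CL: int
    lb: int
    m: int
    ia: int
    ta: int
    tau: int
    c_rho: int


class RhoContext:
    """Precomputed ancestor-side state for repeated metric evaluation.

    Building the breakpoint graph anew for every candidate genome only
    requires the descendant-side pass once the gray structure, the
    ancestor telomere table and the gray-only union-find are frozen.
    """

    def __init__(self, rho: Genome, n: int | None = None):
        self.rho = rho
        self.n = max(rho.n, n or 0)
        V = 2 * self.n
        self.gray = gray_edges_of(rho)
        self.gray_covered = bytearray(V)
        for u, v in self.gray:
            self.gray_covered[u] = 1
            self.gray_covered[v] = 1
        self.rho_tel = telomere_table(rho) + [0] * (V - 2 * rho.n)
        self.rho_mult = multiplicity_table(rho)
        uf = UnionFind(V)
        for u, v in self.gray:
            uf.union(u, v)
        self.gray_parents = uf.flat_parents()
        # rho against itself has black edges exactly parallel to the gray
        # ones, so its component count is that of the gray graph alone
        roots = sorted(set(self.gray_parents))
        self.c_rho = len(roots)
        root_index = {r: i for i, r in enumerate(roots)}
        #: compact gray-component index per vertex; black edges can only
        #: merge these components, so C = c_rho - (number of merges)
        self.groot = [root_index[r] for r in self.gray_parents]
        self.T0 = sum(self.rho_tel)
        self.M0 = sum(self.rho_mult)
        # ia(rho,rho) counts junction occurrences incl. chromosome copies
        ia0 = sum(len(ch) - 1 for ch in rho.chromosomes)
        ta0 = 2 * len(rho.chromosomes)
        self.base_adj = 2 * ia0 + ta0
        # gray neighbours per vertex, for candidate generation
        self.gray_neighbors: dict[int, list[int]] = {}
        for u, v in self.gray:
            self.gray_neighbors.setdefault(u, []).append(v)
            self.gray_neighbors.setdefault(v, []).append(u)

    def evaluate(self, chromosomes: Sequence[Chrom]) -> Metrics:
        """Metrics of ``rho`` against a genome given as chromosome tuples."""
        covered = self.gray_covered
        groot = self.groot
        gray = self.gray
        pi_tel: dict[int, int] = {}
        mult: dict[int, int] = {}
        ia = 0
        merges = 0
        loops: list[int] = []
        parent = list(range(self.c_rho))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for ch in chromosomes:
            prev_r = -1
            for x in ch:
                if x > 0:
                    xl = 2 * x - 2
                    xr = xl + 1
                    mult[x] = mult.get(x, 0) + 1
                else:
                    xr = -2 * x - 2
                    xl = xr + 1
                    mult[-x] = mult.get(-x, 0) + 1
                if prev_r >= 0:
                    pair = (prev_r, xl) if prev_r <= xl else (xl, prev_r)
                    if pair in gray:
                        ia += 1
                    if covered[pair[0]] and covered[pair[1]]:
                        if pair[0] == pair[1]:
                            loops.append(pair[0])
                        else:
                            ra, rb = find(groot[pair[0]]), find(groot[pair[1]])
                            if ra != rb:
                                if ra > rb:
                                    ra, rb = rb, ra
                                parent[rb] = ra
                                merges += 1
                prev_r = xr
            first = ch[0]
            v0 = 2 * first - 2 if first > 0 else -2 * first - 1
            pi_tel[v0] = pi_tel.get(v0, 0) + 1
            pi_tel[prev_r] = pi_tel.get(prev_r, 0) + 1

        rho_tel = self.rho_tel
        T = self.T0
        ta = 0
        for v, p in pi_tel.items():
            r = rho_tel[v]
            if r == 0:
                T += p
            else:
                matched = r if r < p else p
                T -= matched
                ta += matched
        m = self.M0
        rho_mult = self.rho_mult
        for x, c in mult.items():
            r = rho_mult[x]
            m += (r - c if r >= c else c - r) - r
        m *= 4

        C = self.c_rho - merges
        loop_per: dict[int, int] = {}
        for v in set(loops):
            r = find(groot[v])
            loop_per[r] = loop_per.get(r, 0) + 1
        L_list = tuple(loop_per[k] for k in sorted(loop_per))
        CL = self.c_rho - C + sum((li + 1) // 2 for li in L_list)
        lb = (T + 1) // 2 + CL
        tau_val = m + self.base_adj - (2 * ia + ta)
        return Metrics(
            T=T, C=C, L=len(set(loops)), L_per_component=L_list, CL=CL, lb=lb,
            m=m, ia=ia, ta=ta, tau=tau_val, c_rho=self.c_rho,
        )


def _context(rho: Genome, pi: Genome) -> RhoContext:
    return RhoContext(rho, n=max(rho.n, pi.n))


def genome_metrics(rho: Genome, pi: Genome) -> Metrics:
    """All metrics of the pair ``(rho, pi)`` in one pass."""
    return _context(rho, pi).evaluate(pi.chromosomes)


def incorrect_telomeres(rho: Genome, pi: Genome) -> int:
    """``T(rho, pi)``: ancestor-telomere deficits plus surplus telomeres."""
    return genome_metrics(rho, pi).T


def lower_bound(rho: Genome, pi: Genome) -> int:
    """The weighted-distance lower bound ``ceil(T/2) + CL``."""
    return genome_metrics(rho, pi).lb


def tau(rho: Genome, pi: Genome) -> int:
    """The auxiliary distance; 0 iff ``pi == rho``."""
    return genome_metrics(rho, pi).tau


def tau_parts(rho: Genome, pi: Genome) -> tuple[int, int, int]:
    """The parts ``(m, ia, ta)`` of tau."""
    mets = genome_metrics(rho, pi)
    return mets.m, mets.ia, mets.ta
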