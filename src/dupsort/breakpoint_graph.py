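"""The extended breakpoint graph of an ancestor/descendant genome pair.

The graph lives on the ``2n`` extremity vertices ``1_t, 1_h, ..., n_t,
n_h``.  Gray edges are the adjacencies of the ancestor ``rho`` (a set:
identical chromosome copies contribute the same edge once); black edges
are the adjacencies of the descendant ``pi`` (a multiset).  A black edge
is suppressed when one of its endpoints carries no gray edge, i.e. is a
telomere of ``rho`` -- those junctions are accounted for by the incorrect
telomere count instead.  A black edge ``(v, v)`` is a loop (caused by a
``x -x`` pattern in ``pi``).

Black edges whose removal disconnects a component (1-bridges), and pairs
of non-bridge black edges whose joint removal does (2-bridges), mark the
junctions where component-increasing inverse DCJs can act.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from ._util import UnionFind
from .genome_model import (
    Extremity,
    Genome,
    end_ids,
    ext_from_id,
    junction_ids,
    validate_ancestor,
)

__all__ = ["BreakpointGraph", "build"]

Edge = tuple[int, int]  # sorted extremity-id pair


class BreakpointGraph:
    """Gray/black multigraph on extremity vertices; see module docstring.

    The id-based attributes (``gray``, ``black``, extremity ids ``0..2n-1``
    with ``2(x-1)`` = tail and ``2(x-1)+1`` = head of element ``x``) are
    the working surface for the sorting machinery; the ``find_*`` methods
    expose :class:`~dupsort.genome_model.Extremity` pairs.
    """

    def __init__(self, n: int, gray: Iterable[Edge], black: Counter):
        self.n = n
        self.gray: frozenset[Edge] = frozenset(gray)
        self.black: Counter = Counter(black)
        self._comp: list[int] | None = None

    # -- components --------------------------------------------------------
    def _components(self) -> list[int]:
        if self._comp is None:
            uf = UnionFind(2 * self.n)
            for u, v in self.gray:
                uf.union(u, v)
            for u, v in self.black:
                uf.union(u, v)
            self._comp = uf.flat_parents()
        return self._comp

    def component_id(self, v: int) -> int:
        return self._components()[v]

    def count_components(self) -> int:
        comp = self._components()
        return len(set(comp))

    def loop_vertices(self) -> list[int]:
        return sorted({u for (u, v) in self.black if u == v})

    def count_loops(self) -> int:
        """Number of vertices carrying at least one loop."""
        return len(self.loop_vertices())

    def loops_per_component(self) -> list[int]:
        """Loop-vertex counts per component, for components that have any."""
        comp = self._components()
        per: Counter = Counter(comp[v] for v in self.loop_vertices())
        return [per[c] for c in sorted(per)]

    # -- bridges ------------------------------------------------------------
    def _adjacency(self, drop: Counter | None = None) -> list[list[tuple[int, int]]]:
        """Adjacency lists of (neighbor, edge_id); parallel edges get
        distinct ids, loops are omitted (they never affect connectivity)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(2 * self.n)]
        eid = 0
        for u, v in self.gray:
            adj[u].append((v, eid))
            adj[v].append((u, eid))
            eid += 1
        for (u, v), mult in self.black.items():
            if u == v:
                continue
            if drop is not None:
                mult -= drop.get((u, v), 0)
            for _ in range(mult):
                adj[u].append((v, eid))
                adj[v].append((u, eid))
                eid += 1
        return adj

    def _graph_bridges(self, drop: Counter | None = None) -> set[Edge]:
        """All bridges of the gray+black graph (iterative lowpoint DFS)."""
        adj = self._adjacency(drop)
        V = 2 * self.n
        disc = [-1] * V
        low = [0] * V
        bridges: set[Edge] = set()
        timer = 0
        for root in range(V):
            if disc[root] != -1:
                continue
            stack = [(root, -1, iter(adj[root]))]
            disc[root] = low[root] = timer
            timer += 1
            while stack:
                v, in_edge, it = stack[-1]
                advanced = False
                for w, eid in it:
                    if eid == in_edge:
                        continue
                    if disc[w] == -1:
                        disc[w] = low[w] = timer
                        timer += 1
                        stack.append((w, eid, iter(adj[w])))
                        advanced = True
                        break
                    low[v] = min(low[v], disc[w])
                if not advanced:
                    stack.pop()
                    if stack:
                        p = stack[-1][0]
                        low[p] = min(low[p], low[v])
                        if low[v] > disc[p]:
                            e = (p, v) if p <= v else (v, p)
                            bridges.add(e)
        return bridges

    def one_bridge_edges(self) -> list[Edge]:
        """Black 1-bridges as sorted extremity-id pairs."""
        bridges = self._graph_bridges()
        out = []
        for e, mult in self.black.items():
            if mult == 1 and e[0] != e[1] and e not in self.gray and e in bridges:
                out.append(e)
        return sorted(out)

    def two_bridge_edges(self) -> list[tuple[Edge, Edge]]:
        """Pairs of non-1-bridge black edges whose joint removal increases
        the component count; both edges lie in the same component.  A
        multiplicity-2 black edge may pair with itself."""
        comp = self._components()
        ones = set(self.one_bridge_edges())
        cands = [
            e for e, mult in self.black.items()
            if e[0] != e[1] and e not in ones and (mult == 1 or True)
        ]
        pairs: list[tuple[Edge, Edge]] = []
        seen: set[tuple[Edge, Edge]] = set()
        for i, e1 in enumerate(cands):
            # bridges of the graph minus one copy of e1: each pairs with e1
            if e1 in self.gray:
                continue  # a gray-parallel edge can never be part of a cut
            sub_bridges = self._graph_bridges(drop=Counter({e1: 1}))
            partners = []
            if self.black[e1] >= 2 and e1 in sub_bridges:
                partners.append(e1)
            for e2 in cands:
                if e2 == e1 or e2 in self.gray:
                    continue
                if self.black[e2] == 1 and e2 in sub_bridges and comp[e2[0]] == comp[e1[0]]:
                    partners.append(e2)
            for e2 in partners:
                key = (e1, e2) if e1 <= e2 else (e2, e1)
                if key not in seen:
                    seen.add(key)
                    pairs.append(key)
        return sorted(pairs)

    # -- public, Extremity-typed views --------------------------------------
    def find_1_bridges(self) -> list[tuple[Extremity, Extremity]]:
        return [(ext_from_id(u), ext_from_id(v)) for u, v in self.one_bridge_edges()]

    def find_2_bridges(self) -> list[tuple[tuple[Extremity, Extremity], tuple[Extremity, Extremity]]]:
        return [
            ((ext_from_id(a), ext_from_id(b)), (ext_from_id(c), ext_from_id(d)))
            for (a, b), (c, d) in self.two_bridge_edges()
        ]

    def to_dot(self) -> str:
        """DOT export for debugging: gray dashed, black solid, multiplicity
        labels on black edges."""
        lines = ["graph breakpoint_graph {"]
        for v in range(2 * self.n):
            lines.append(f'  v{v} [label="{ext_from_id(v)}"];')
        for u, v in sorted(self.gray):
            lines.append(f"  v{u} -- v{v} [style=dashed];")
        for (u, v), mult in sorted(self.black.items()):
            label = f' [label="x{mult}"]' if mult > 1 else ""
            lines.append(f"  v{u} -- v{v}{label};")
        lines.append("}")
        return "\n".join(lines)


def gray_edges_of(rho: Genome) -> set[Edge]:
    """Adjacency set of the ancestor (duplicate chromosomes collapse)."""
    return {pair for ch in rho.counts for pair in junction_ids(ch)}


def black_edges_of(pi: Genome, gray_covered: set[int]) -> Counter:
    """Adjacency multiset of the descendant; pairs touching an uncovered
    vertex (an ancestor telomere) are suppressed."""
    black: Counter = Counter()
    for ch in pi.chromosomes:
        for u, v in junction_ids(ch):
            if u in gray_covered and v in gray_covered:
                black[(u, v)] += 1
    return black


def build(rho: Genome, pi: Genome, check: bool = True) -> BreakpointGraph:
    """Build the breakpoint graph of ``(rho, pi)``.

    ``check`` enforces the ancestor constraint on ``rho``.
    """
    if check:
        validate_ancestor(rho).raise_for_violations()
    n = max(rho.n, pi.n)
    gray = gray_edges_of(rho)
    covered = {v for e in gray for v in e}
    black = black_edges_of(pi, covered)
    return BreakpointGraph(n, gray, black)


# re-exported telomere helper for callers assembling contexts
def rho_telomere_ids(rho: Genome) -> Counter:
    tel: Counter = Counter()
    for ch in rho.chromosomes:
        a, b = end_ids(ch)
        tel[a] += 1
        tel[b] += 1
    return tel
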