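"""Small shared helpers."""

from __future__ import annotations


class UnionFind:
    """Array union-find with path halving and union by size."""

    __slots__ = ("parent", "size")

    def __init__(self, n: int, parent: list[int] | None = None):
        self.parent = list(range(n)) if parent is None else list(parent)
        self.size = None  # size bookkeeping is skipped when seeded

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if ra > rb:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True

    def n_components(self) -> int:
        p = self.parent
        return sum(1 for i, pi in enumerate(p) if self.find(i) == i)

    def flat_parents(self) -> list[int]:
        """Fully path-compressed parent array (usable to seed copies)."""
        return [self.find(i) for i in range(len(self.parent))]
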