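"""Genomes as multisets of signed chromosomes.

A chromosome is a non-empty sequence of signed synteny-block identifiers
over the alphabet ``{1..n}``; the sign encodes reading direction.  A
chromosome and its reflection (reversed order, all signs flipped) denote
the same molecule, so every chromosome is stored in a canonical form: the
lexicographically smaller of the sequence and its reflection.  A genome is
a multiset of such chromosomes -- identical chromosomes (homologs) may be
present in several copies.

Every element ``x`` has two extremities, the tail ``x_t`` and the head
``x_h``.  Reading a positively oriented element yields tail-then-head;
a negative orientation swaps them.  Extremities at chromosome ends are
telomeres.  Two consecutive extremities of different elements form a
junction; junctions and telomeres are classified against a reference
genome into adjacencies (also present there) and breakpoints (novel).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

__all__ = [
    "GenomeError",
    "AncestorConstraintError",
    "Extremity",
    "Genome",
    "reflect",
    "canonical",
    "canonical_flag",
    "multiplicity",
    "telomere_count",
    "adjacencies",
    "classify_breakpoints",
    "validate_ancestor",
    "AncestorValidation",
    "BreakpointClassification",
]


class GenomeError(ValueError):
    """Raised for malformed chromosomes or out-of-range element ids."""


class AncestorConstraintError(GenomeError):
    """Raised when a genome violates the ancestor constraint."""


Chrom = tuple[int, ...]


def reflect(chromosome: Sequence[int]) -> Chrom:
    """Reversed chromosome with every orientation flipped."""
    return tuple(-x for x in reversed(chromosome))


def _chrom_key(c: Chrom) -> tuple:
    # order by id first, forward orientation before reverse, so that the
    # canonical form of (1, 2, 3) is (1, 2, 3) rather than (-3, -2, -1)
    return tuple((abs(x), x < 0) for x in c)


def canonical(chromosome: Sequence[int]) -> Chrom:
    """Canonical representative of a chromosome modulo reflection: the
    smaller of the sequence and its reflection under id-then-orientation
    lexicographic order."""
    c = tuple(chromosome)
    r = reflect(c)
    return c if _chrom_key(c) <= _chrom_key(r) else r


def canonical_flag(chromosome: Sequence[int]) -> tuple[Chrom, bool]:
    """Canonical form plus whether canonicalization reflected the input."""
    c = tuple(chromosome)
    r = reflect(c)
    return (c, False) if _chrom_key(c) <= _chrom_key(r) else (r, True)


class Extremity(NamedTuple):
    """One end of an element: the tail ``x_t`` or the head ``x_h``."""

    element: int
    head: bool

    def __str__(self) -> str:  # e.g. "3t", "5h"
        return f"{self.element}{'h' if self.head else 't'}"

    @classmethod
    def tail(cls, element: int) -> "Extremity":
        return cls(element, False)

    @classmethod
    def head_of(cls, element: int) -> "Extremity":
        return cls(element, True)

    @classmethod
    def parse(cls, text: str) -> "Extremity":
        text = text.strip()
        if len(text) < 2 or text[-1] not in "th":
            raise ValueError(f"cannot parse extremity {text!r}")
        return cls(int(text[:-1]), text[-1] == "h")


# --- integer extremity encoding, shared by the graph/metrics internals ---
# tail of x -> 2*(x-1), head of x -> 2*(x-1)+1

def ext_id(element: int, head: bool) -> int:
    return 2 * (element - 1) + (1 if head else 0)


def left_ext_id(signed: int) -> int:
    """Extremity read first for a signed element occurrence."""
    return ext_id(signed, False) if signed > 0 else ext_id(-signed, True)


def right_ext_id(signed: int) -> int:
    """Extremity read last for a signed element occurrence."""
    return ext_id(signed, True) if signed > 0 else ext_id(-signed, False)


def ext_from_id(v: int) -> Extremity:
    return Extremity(v // 2 + 1, bool(v % 2))


def junction_ids(chromosome: Sequence[int]) -> list[tuple[int, int]]:
    """Sorted extremity-id pairs of all junctions of one chromosome."""
    out = []
    for a, b in zip(chromosome, chromosome[1:]):
        u, v = right_ext_id(a), left_ext_id(b)
        out.append((u, v) if u <= v else (v, u))
    return out


def end_ids(chromosome: Sequence[int]) -> tuple[int, int]:
    """Extremity ids of the two telomeres of one chromosome."""
    return left_ext_id(chromosome[0]), right_ext_id(chromosome[-1])


class Genome:
    """A multiset of canonical chromosomes over ``{1..n}``.

    Parameters
    ----------
    chromosomes:
        Iterable of chromosomes (iterables of nonzero signed ints).
    n:
        Alphabet size.  Defaults to the largest absolute id observed.
    """

    __slots__ = ("chromosomes", "n", "_counts")

    chromosomes: tuple[Chrom, ...]
    n: int

    def __init__(self, chromosomes: Iterable[Sequence[int]], n: int | None = None):
        canon = []
        max_id = 0
        for ch in chromosomes:
            c = tuple(ch)
            if not c:
                raise GenomeError("empty chromosome")
            for x in c:
                if not isinstance(x, int) or x == 0:
                    raise GenomeError(f"invalid element {x!r}: ids are nonzero ints")
                max_id = max(max_id, abs(x))
            canon.append(canonical(c))
        if n is None:
            n = max_id
        elif max_id > n:
            raise GenomeError(f"element id {max_id} exceeds alphabet size n={n}")
        object.__setattr__(self, "chromosomes", tuple(sorted(canon)))
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "_counts", None)

    def __setattr__(self, name, value):  # immutable
        raise AttributeError("Genome is immutable")

    @classmethod
    def _trusted(cls, canonical_chromosomes: Iterable[Chrom], n: int) -> "Genome":
        """Fast path for internal callers whose chromosomes are already
        canonical and whose ids are known to be within the alphabet."""
        g = object.__new__(cls)
        object.__setattr__(g, "chromosomes", tuple(sorted(canonical_chromosomes)))
        object.__setattr__(g, "n", n)
        object.__setattr__(g, "_counts", None)
        return g

    # -- container protocol ------------------------------------------------
    def __iter__(self) -> Iterator[Chrom]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Genome)
            and self.chromosomes == other.chromosomes
            and self.n == other.n
        )

    def __hash__(self) -> int:
        return hash((self.chromosomes, self.n))

    def __repr__(self) -> str:
        body = "; ".join(" ".join(str(x) for x in ch) for ch in self.chromosomes)
        return f"Genome({body!r}, n={self.n})"

    # -- queries -----------------------------------------------------------
    @property
    def counts(self) -> Counter:
        """Multiset counts of canonical chromosomes."""
        if self._counts is None:
            object.__setattr__(self, "_counts", Counter(self.chromosomes))
        return self._counts

    def with_chromosomes(self, chromosomes: Iterable[Sequence[int]]) -> "Genome":
        return Genome(chromosomes, n=self.n)

    def multiplicity(self, x: int) -> int:
        return multiplicity(self, x)

    def telomere_count(self, e: Extremity) -> int:
        return telomere_count(self, e)

    def adjacencies(self) -> Counter:
        return adjacencies(self)


def multiplicity(g: Genome, x: int) -> int:
    """Number of occurrences of element ``x`` in ``g``, in any orientation."""
    if not 1 <= x <= g.n:
        raise GenomeError(f"element id {x} outside 1..{g.n}")
    return sum(1 for ch in g.chromosomes for e in ch if abs(e) == x)


def multiplicity_table(g: Genome) -> list[int]:
    """``mult(g, x)`` for every ``x``, indexed ``1..n`` (slot 0 unused)."""
    table = [0] * (g.n + 1)
    for ch in g.chromosomes:
        for e in ch:
            table[abs(e)] += 1
    return table


def telomere_table(g: Genome) -> list[int]:
    """``t(g, e)`` for every extremity id ``0..2n-1``."""
    table = [0] * (2 * g.n)
    for ch in g.chromosomes:
        a, b = end_ids(ch)
        table[a] += 1
        table[b] += 1
    return table


def telomere_count(g: Genome, e: Extremity) -> int:
    """How often extremity ``e`` occurs as a chromosome end of ``g``."""
    if not 1 <= e.element <= g.n:
        raise GenomeError(f"element id {e.element} outside 1..{g.n}")
    return telomere_table(g)[ext_id(e.element, e.head)]


def adjacencies(g: Genome) -> Counter:
    """Multiset of junctions of ``g`` as unordered :class:`Extremity` pairs.

    Consecutive extremities belonging to the same element (co-elements)
    are not junctions and are skipped.
    """
    out: Counter = Counter()
    for ch in g.chromosomes:
        for u, v in junction_ids(ch):
            out[(ext_from_id(u), ext_from_id(v))] += 1
    return out


@dataclass(frozen=True)
class BreakpointClassification:
    """Junctions and chromosome ends of ``pi`` classified against ``rho``."""

    inner_adjacencies: tuple[tuple[Extremity, Extremity], ...]
    inner_breakpoints: tuple[tuple[Extremity, Extremity], ...]
    telomere_adjacencies: tuple[Extremity, ...]
    telomere_breakpoints: tuple[Extremity, ...]


def classify_breakpoints(rho: Genome, pi: Genome) -> BreakpointClassification:
    """Classify every junction and end of ``pi`` relative to ``rho``.

    A junction of ``pi`` is an inner adjacency iff the same unordered
    extremity pair is consecutive in some chromosome of ``rho``; a
    chromosome end of ``pi`` is a telomere adjacency iff the extremity is
    a telomere somewhere in ``rho``.  Both are reported per occurrence.
    """
    rho_adj = {pair for ch in rho.chromosomes for pair in junction_ids(ch)}
    rho_tel = telomere_table(rho) if rho.n else []
    ia, ib, ta, tb = [], [], [], []
    for ch in pi.chromosomes:
        for u, v in junction_ids(ch):
            pair = (ext_from_id(u), ext_from_id(v))
            (ia if (u, v) in rho_adj else ib).append(pair)
        for v in end_ids(ch):
            e = ext_from_id(v)
            if v < len(rho_tel) and rho_tel[v] > 0:
                ta.append(e)
            else:
                tb.append(e)
    return BreakpointClassification(tuple(ia), tuple(ib), tuple(ta), tuple(tb))


@dataclass(frozen=True)
class AncestorValidation:
    ok: bool
    violations: tuple[str, ...]

    def raise_for_violations(self) -> None:
        if not self.ok:
            raise AncestorConstraintError("; ".join(self.violations))


def validate_ancestor(rho: Genome) -> AncestorValidation:
    """Check the ancestor constraint on ``rho``.

    Two distinct chromosomes must be disjoint (no element id in common) or
    identical modulo reflection, and every id in ``1..n`` must occur.
    Identical copies are collapsed by canonicalization, so only distinct
    canonical chromosomes are compared pairwise.
    """
    violations: list[str] = []
    distinct = sorted(rho.counts)
    contents = [frozenset(abs(x) for x in ch) for ch in distinct]
    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            shared = contents[i] & contents[j]
            if shared:
                violations.append(
                    f"chromosomes {distinct[i]} and {distinct[j]} are neither "
                    f"disjoint nor identical (shared ids {sorted(shared)})"
                )
    present = set().union(*contents) if contents else set()
    missing = [x for x in range(1, rho.n + 1) if x not in present]
    if missing:
        violations.append(f"elements absent from the ancestor: {missing}")
    return AncestorValidation(not violations, tuple(violations))
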