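"""Evolutionary operations on genomes and their inverses.

Eleven operation kinds are modelled: reversal, transposition, inverted
transposition, fusion, fission, translocation, tandem duplication,
transposition duplication, deletion, chromosome duplication and
chromosome deletion.  All have weight 1 except (inverted) transpositions
and transposition duplications, which have weight 2.  Two auxiliary kinds
-- insertion and chromosome insertion -- exist only as the inverses of
the two deletion kinds; a sorting sequence running from descendant to
ancestor uses them, and reversing it yields deletions again.

Chromosomes are addressed by their canonical form (see
:mod:`dupsort.genome_model`); identical copies are interchangeable, so a
canonical key plus the multiset count addresses operations unambiguously.
All positions are 0-based; segments are half-open ``[start, end)`` over
element indices, cut positions range over ``0..len``.

The content-preserving operations are also expressible through the
double cut and join (DCJ) operator: one DCJ realizes a reversal,
translocation, fusion or fission; a transposition needs two DCJs with a
transient circular intermediate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .genome_model import Chrom, Genome, canonical, canonical_flag, reflect

__all__ = [
    "OpKind",
    "Operation",
    "OperationError",
    "apply",
    "invert",
    "DCJ",
    "apply_dcj",
    "apply_dcj_sequence",
    "dcjs_for_transposition",
]


class OperationError(ValueError):
    """Raised when an operation's parameters do not fit the genome."""


class OpKind(enum.Enum):
    REVERSAL = "reversal"
    TRANSPOSITION = "transposition"
    INVERTED_TRANSPOSITION = "inverted_transposition"
    FUSION = "fusion"
    FISSION = "fission"
    TRANSLOCATION = "translocation"
    TANDEM_DUPLICATION = "tandem_duplication"
    TRANSPOSITION_DUPLICATION = "transposition_duplication"
    DELETION = "deletion"
    CHROMOSOME_DUPLICATION = "chromosome_duplication"
    CHROMOSOME_DELETION = "chromosome_deletion"
    # inverse-only kinds
    INSERTION = "insertion"
    CHROMOSOME_INSERTION = "chromosome_insertion"


#: weight 2 for the transposition-like operations, 1 otherwise
WEIGHTS = {
    OpKind.TRANSPOSITION: 2,
    OpKind.INVERTED_TRANSPOSITION: 2,
    OpKind.TRANSPOSITION_DUPLICATION: 2,
}

#: deterministic rank used for tie-breaking between equal-score candidates
KIND_RANK = {kind: i for i, kind in enumerate(OpKind)}


@dataclass(frozen=True)
class Operation:
    """A typed, parameterized, weighted rearrangement event."""

    kind: OpKind
    chrom: Chrom | None = None
    chrom_b: Chrom | None = None
    start: int | None = None
    end: int | None = None
    insert: int | None = None
    pos: int | None = None
    pos_b: int | None = None
    reflect_a: bool = False
    reflect_b: bool = False
    segment: Chrom | None = None

    @property
    def weight(self) -> int:
        return WEIGHTS.get(self.kind, 1)

    def sort_key(self):
        """Total deterministic order: kind rank, then parameters."""
        return (
            KIND_RANK[self.kind],
            self.chrom or (),
            self.chrom_b or (),
            self.start if self.start is not None else -1,
            self.end if self.end is not None else -1,
            self.insert if self.insert is not None else -1,
            self.pos if self.pos is not None else -1,
            self.pos_b if self.pos_b is not None else -1,
            self.reflect_a,
            self.reflect_b,
            self.segment or (),
        )

    def params(self) -> dict:
        out: dict = {}
        for name in ("chrom", "chrom_b", "segment"):
            v = getattr(self, name)
            if v is not None:
                out[name] = list(v)
        for name in ("start", "end", "insert", "pos", "pos_b"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        for name in ("reflect_a", "reflect_b"):
            if getattr(self, name):
                out[name] = True
        return out

    @classmethod
    def from_params(cls, kind: str | OpKind, params: dict) -> "Operation":
        kw = dict(params)
        for name in ("chrom", "chrom_b", "segment"):
            if name in kw and kw[name] is not None:
                kw[name] = tuple(kw[name])
        return cls(kind=OpKind(kind) if isinstance(kind, str) else kind, **kw)


# ---------------------------------------------------------------------------
# application

@dataclass(frozen=True)
class _Result:
    """One output chromosome: raw sequence, canonical form, reflected flag."""

    raw: Chrom
    canon: Chrom
    reflected: bool


def _make_result(raw: Sequence[int]) -> _Result:
    canon, refl = canonical_flag(raw)
    return _Result(tuple(raw), canon, refl)


@dataclass(frozen=True)
class ApplyInfo:
    removed: tuple[Chrom, ...]
    results: tuple[_Result, ...]


def _need(g: Genome, key: Chrom, count: int = 1) -> None:
    if g.counts.get(key, 0) < count:
        raise OperationError(f"genome lacks {count} copies of chromosome {key}")


def _span(op_name: str, s, e, length, allow_full=True) -> None:
    if s is None or e is None or not (0 <= s < e <= length):
        raise OperationError(f"{op_name}: invalid segment [{s}, {e}) on length {length}")
    if not allow_full and e - s == length:
        raise OperationError(f"{op_name}: segment may not span the whole chromosome")


def _rebuild(g: Genome, removed: Sequence[Chrom], added: Sequence[Chrom]) -> Genome:
    chroms = list(g.chromosomes)
    for key in removed:
        try:
            chroms.remove(key)
        except ValueError:
            raise OperationError(f"genome lacks chromosome {key}") from None
    chroms.extend(added)
    if not chroms:
        raise OperationError("operation would leave an empty genome")
    # existing chromosomes are canonical by the Genome invariant and the
    # added ones were canonicalized in _make_result, so skip revalidation
    n = g.n
    for ch in added:
        for x in ch:
            if abs(x) > n:
                n = abs(x)
    return Genome._trusted(chroms, n)


def apply_detailed(op: Operation, g: Genome) -> tuple[Genome, ApplyInfo]:
    """Apply ``op`` to ``g``; also report raw results and reflection flags.

    The extra information lets callers map positions through the
    canonicalization step, which may reflect an output chromosome.
    """
    k = op.kind
    removed: tuple[Chrom, ...]
    raws: list[Chrom]

    if k is OpKind.REVERSAL:
        K = op.chrom
        _need(g, K)
        _span("reversal", op.start, op.end, len(K))
        removed = (K,)
        raws = [K[: op.start] + reflect(K[op.start : op.end]) + K[op.end :]]

    elif k in (OpKind.TRANSPOSITION, OpKind.INVERTED_TRANSPOSITION):
        K = op.chrom
        _need(g, K)
        _span(k.value, op.start, op.end, len(K), allow_full=False)
        seg = K[op.start : op.end]
        base = K[: op.start] + K[op.end :]
        ins = op.insert
        if ins is None or not 0 <= ins <= len(base):
            raise OperationError(f"{k.value}: invalid insertion index {ins}")
        if k is OpKind.TRANSPOSITION and ins == op.start:
            raise OperationError("transposition: reinsertion at the excision point is the identity")
        if k is OpKind.INVERTED_TRANSPOSITION:
            seg = reflect(seg)
        removed = (K,)
        raws = [base[:ins] + seg + base[ins:]]

    elif k is OpKind.FUSION:
        Ka, Kb = op.chrom, op.chrom_b
        if Ka == Kb:
            _need(g, Ka, 2)
        else:
            _need(g, Ka)
            _need(g, Kb)
        a = reflect(Ka) if op.reflect_a else Ka
        b = reflect(Kb) if op.reflect_b else Kb
        removed = (Ka, Kb)
        raws = [a + b]

    elif k is OpKind.FISSION:
        K = op.chrom
        _need(g, K)
        if op.pos is None or not 0 < op.pos < len(K):
            raise OperationError(f"fission: cut {op.pos} must be strictly inside 0..{len(K)}")
        removed = (K,)
        raws = [K[: op.pos], K[op.pos :]]

    elif k is OpKind.TRANSLOCATION:
        Ka, Kb = op.chrom, op.chrom_b
        if Ka == Kb:
            _need(g, Ka, 2)
        else:
            _need(g, Ka)
            _need(g, Kb)
        a = reflect(Ka) if op.reflect_a else Ka
        b = reflect(Kb) if op.reflect_b else Kb
        pa, pb = op.pos, op.pos_b
        if pa is None or pb is None or not (0 <= pa <= len(a) and 0 <= pb <= len(b)):
            raise OperationError(f"translocation: invalid cuts {pa}, {pb}")
        r1, r2 = a[:pa] + b[pb:], b[:pb] + a[pa:]
        if not r1 or not r2:
            raise OperationError("translocation: a result is empty (use fusion/fission)")
        removed = (Ka, Kb)
        raws = [r1, r2]

    elif k is OpKind.TANDEM_DUPLICATION:
        K = op.chrom
        _need(g, K)
        _span("tandem_duplication", op.start, op.end, len(K))
        removed = (K,)
        raws = [K[: op.end] + K[op.start : op.end] + K[op.end :]]

    elif k is OpKind.TRANSPOSITION_DUPLICATION:
        Ks, Kd = op.chrom, op.chrom_b
        _need(g, Ks)
        if Kd != Ks:
            _need(g, Kd)
        _span("transposition_duplication", op.start, op.end, len(Ks))
        # a chromosome equals its reflection, so the copied segment may be
        # read from either strand of the source (reflect_a)
        src = reflect(Ks) if op.reflect_a else Ks
        seg = src[op.start : op.end]
        ins = op.insert
        if ins is None or not 0 <= ins <= len(Kd):
            raise OperationError(f"transposition_duplication: invalid insertion index {ins}")
        removed = (Kd,)
        raws = [Kd[:ins] + seg + Kd[ins:]]

    elif k is OpKind.DELETION:
        K = op.chrom
        _need(g, K)
        _span("deletion", op.start, op.end, len(K))
        removed = (K,)
        rest = K[: op.start] + K[op.end :]
        raws = [rest] if rest else []

    elif k is OpKind.CHROMOSOME_DUPLICATION:
        _need(g, op.chrom)
        removed = ()
        raws = [op.chrom]

    elif k is OpKind.CHROMOSOME_DELETION:
        _need(g, op.chrom)
        removed = (op.chrom,)
        raws = []

    elif k is OpKind.INSERTION:
        seg = op.segment
        if not seg:
            raise OperationError("insertion: empty segment")
        if op.chrom is None:
            removed = ()
            raws = [tuple(seg)]
        else:
            K = op.chrom
            _need(g, K)
            if op.pos is None or not 0 <= op.pos <= len(K):
                raise OperationError(f"insertion: invalid position {op.pos}")
            removed = (K,)
            raws = [K[: op.pos] + tuple(seg) + K[op.pos :]]

    elif k is OpKind.CHROMOSOME_INSERTION:
        if not op.segment:
            raise OperationError("chromosome_insertion: empty segment")
        removed = ()
        raws = [tuple(op.segment)]

    else:  # pragma: no cover
        raise OperationError(f"unknown operation kind {k}")

    results = tuple(_make_result(r) for r in raws)
    g2 = _rebuild(g, removed, [r.canon for r in results])
    return g2, ApplyInfo(removed, results)


def apply(op: Operation, g: Genome) -> Genome:
    """Return ``op(g)``."""
    return apply_detailed(op, g)[0]


# ---------------------------------------------------------------------------
# inversion

def _mpos(p: int, length: int, reflected: bool) -> int:
    return length - p if reflected else p


def _mspan(s: int, e: int, length: int, reflected: bool) -> tuple[int, int]:
    return (length - e, length - s) if reflected else (s, e)


def invert(op: Operation, g_before: Genome) -> Operation:
    """The operation undoing ``op``: ``invert(op, g)(op(g)) == g``.

    Weights follow the kind mapping: content-preserving kinds invert
    within their own kind, duplications invert to (weight-1) deletions of
    the copy, deletions invert to insertions.
    """
    _, info = apply_detailed(op, g_before)
    k = op.kind
    res = info.results

    if k is OpKind.REVERSAL:
        r = res[0]
        s, e = _mspan(op.start, op.end, len(r.raw), r.reflected)
        return Operation(OpKind.REVERSAL, chrom=r.canon, start=s, end=e)

    if k in (OpKind.TRANSPOSITION, OpKind.INVERTED_TRANSPOSITION):
        r = res[0]
        L = op.end - op.start
        m = len(r.raw)
        if r.reflected:
            s2, e2 = m - (op.insert + L), m - op.insert
            ins2 = (m - L) - op.start
        else:
            s2, e2 = op.insert, op.insert + L
            ins2 = op.start
        return Operation(k, chrom=r.canon, start=s2, end=e2, insert=ins2)

    if k is OpKind.FUSION:
        r = res[0]
        cut = len(op.chrom)
        return Operation(OpKind.FISSION, chrom=r.canon, pos=_mpos(cut, len(r.raw), r.reflected))

    if k is OpKind.FISSION:
        p, q = res
        return Operation(
            OpKind.FUSION, chrom=p.canon, chrom_b=q.canon,
            reflect_a=p.reflected, reflect_b=q.reflected,
        )

    if k is OpKind.TRANSLOCATION:
        r1, r2 = res
        return Operation(
            OpKind.TRANSLOCATION, chrom=r1.canon, chrom_b=r2.canon,
            pos=op.pos, pos_b=op.pos_b, reflect_a=r1.reflected, reflect_b=r2.reflected,
        )

    if k is OpKind.TANDEM_DUPLICATION:
        r = res[0]
        L = op.end - op.start
        s, e = _mspan(op.end, op.end + L, len(r.raw), r.reflected)
        return Operation(OpKind.DELETION, chrom=r.canon, start=s, end=e)

    if k is OpKind.TRANSPOSITION_DUPLICATION:
        r = res[0]
        L = op.end - op.start
        s, e = _mspan(op.insert, op.insert + L, len(r.raw), r.reflected)
        return Operation(OpKind.DELETION, chrom=r.canon, start=s, end=e)

    if k is OpKind.DELETION:
        seg = op.chrom[op.start : op.end]
        if not res:  # the whole chromosome was removed
            return Operation(OpKind.CHROMOSOME_INSERTION, segment=op.chrom)
        r = res[0]
        if r.reflected:
            return Operation(
                OpKind.INSERTION, chrom=r.canon,
                pos=len(r.raw) - op.start, segment=reflect(seg),
            )
        return Operation(OpKind.INSERTION, chrom=r.canon, pos=op.start, segment=seg)

    if k is OpKind.CHROMOSOME_DUPLICATION:
        return Operation(OpKind.CHROMOSOME_DELETION, chrom=op.chrom)

    if k is OpKind.CHROMOSOME_DELETION:
        return Operation(OpKind.CHROMOSOME_INSERTION, segment=op.chrom)

    if k is OpKind.INSERTION:
        if op.chrom is None:
            return Operation(OpKind.CHROMOSOME_DELETION, chrom=canonical(op.segment))
        r = res[0]
        L = len(op.segment)
        s, e = _mspan(op.pos, op.pos + L, len(r.raw), r.reflected)
        return Operation(OpKind.DELETION, chrom=r.canon, start=s, end=e)

    if k is OpKind.CHROMOSOME_INSERTION:
        return Operation(OpKind.CHROMOSOME_DELETION, chrom=canonical(op.segment))

    raise OperationError(f"cannot invert kind {k}")  # pragma: no cover


# ---------------------------------------------------------------------------
# DCJ engine

def canonical_circular(seq: Sequence[int]) -> Chrom:
    """Canonical representative of a circular chromosome: the smallest
    rotation over both strands."""
    seq = tuple(seq)
    best = None
    for strand in (seq, reflect(seq)):
        for i in range(len(strand)):
            rot = strand[i:] + strand[:i]
            if best is None or rot < best:
                best = rot
    return best


def linearize_circular(cc: Chrom, pos: int, reflected: bool) -> Chrom:
    """Cut a circular chromosome before index ``pos``; optionally read the
    other strand."""
    lin = cc[pos:] + cc[:pos]
    return reflect(lin) if reflected else lin


def find_circular_cut(cc: Chrom, target: Chrom) -> tuple[int, bool]:
    for refl in (False, True):
        for pos in range(len(cc)):
            if linearize_circular(cc, pos, refl) == target:
                return pos, refl
    raise OperationError(f"{target} is not a linearization of circular {cc}")


@dataclass(frozen=True)
class DCJ:
    """A double cut and join on one or two chromosomes.

    ``mode``:

    - ``reversal``  -- one linear chromosome, cuts at ``pos_a < pos_b``,
      rejoin with the middle fragment inverted.
    - ``split``     -- one cut at ``pos_a``; the loose ends become telomeres
      (fission).  The second "cut" is at a telomere.
    - ``join``      -- two chromosomes cut at ``pos_a``/``pos_b``; rejoin
      head fragment of the first with tail fragment of the second and vice
      versa (translocation; fusion when the empty fragments vanish).
    - ``join_reflect`` -- as ``join`` but the second chromosome's fragments
      are reflected before rejoining.
    - ``excise``    -- one chromosome, cuts at ``pos_a < pos_b``; the middle
      fragment closes into a circular intermediate.
    - ``reintegrate`` -- cut a linear chromosome at ``pos_a`` and a circular
      chromosome before ``pos_b`` (strand per ``reflect_b``); splice the
      linearized circle in.
    """

    mode: str
    chrom_a: Chrom
    pos_a: int
    chrom_b: Chrom | None = None
    pos_b: int | None = None
    reflect_b: bool = False


def _apply_dcj_state(d: DCJ, linear: list[Chrom], circular: list[Chrom]) -> None:
    def take(pool: list[Chrom], key: Chrom) -> None:
        try:
            pool.remove(key)
        except ValueError:
            raise OperationError(f"no chromosome {key} in current state") from None

    A = d.chrom_a
    if d.mode == "reversal":
        take(linear, A)
        s, e = d.pos_a, d.pos_b
        if not 0 <= s < e <= len(A):
            raise OperationError("reversal DCJ: bad cuts")
        linear.append(canonical(A[:s] + reflect(A[s:e]) + A[e:]))
    elif d.mode == "split":
        take(linear, A)
        p = d.pos_a
        if not 0 < p < len(A):
            raise OperationError("split DCJ: bad cut")
        linear.append(canonical(A[:p]))
        linear.append(canonical(A[p:]))
    elif d.mode in ("join", "join_reflect"):
        B = d.chrom_b
        take(linear, A)
        take(linear, B)
        pa, pb = d.pos_a, d.pos_b
        if not (0 <= pa <= len(A) and 0 <= pb <= len(B)):
            raise OperationError("join DCJ: bad cuts")
        if d.mode == "join":
            r1, r2 = A[:pa] + B[pb:], B[:pb] + A[pa:]
        else:
            r1, r2 = A[:pa] + reflect(B[:pb]), reflect(A[pa:]) + B[pb:]
        for r in (r1, r2):
            if r:
                linear.append(canonical(r))
    elif d.mode == "excise":
        take(linear, A)
        s, e = d.pos_a, d.pos_b
        if not (0 <= s < e <= len(A) and e - s < len(A)):
            raise OperationError("excise DCJ: bad cuts")
        rest = A[:s] + A[e:]
        linear.append(canonical(rest))
        circular.append(canonical_circular(A[s:e]))
    elif d.mode == "reintegrate":
        B = d.chrom_b
        take(linear, A)
        take(circular, B)
        seg = linearize_circular(B, d.pos_b, d.reflect_b)
        p = d.pos_a
        if not 0 <= p <= len(A):
            raise OperationError("reintegrate DCJ: bad cut")
        linear.append(canonical(A[:p] + seg + A[p:]))
    else:
        raise OperationError(f"unknown DCJ mode {d.mode}")


def apply_dcj_sequence(dcjs: Sequence[DCJ], g: Genome) -> Genome:
    """Apply a sequence of DCJs; circular intermediates are allowed between
    steps but must be resolved by the end."""
    linear = list(g.chromosomes)
    circular: list[Chrom] = []
    for d in dcjs:
        _apply_dcj_state(d, linear, circular)
    if circular:
        raise OperationError("DCJ sequence leaves a circular chromosome")
    return g.with_chromosomes(linear)


def apply_dcj(d: DCJ, g: Genome) -> Genome:
    """Apply a single DCJ that keeps the genome linear."""
    return apply_dcj_sequence([d], g)


def dcjs_for_transposition(op: Operation, g: Genome) -> list[DCJ]:
    """The two DCJs (excision, reintegration) realizing a transposition."""
    if op.kind not in (OpKind.TRANSPOSITION, OpKind.INVERTED_TRANSPOSITION):
        raise OperationError("expected a transposition kind")
    K = op.chrom
    _need(g, K)
    seg = K[op.start : op.end]
    base = canonical(K[: op.start] + K[op.end :])
    if op.kind is OpKind.INVERTED_TRANSPOSITION:
        seg = reflect(seg)
    cc = canonical_circular(seg)
    cut, refl = find_circular_cut(cc, seg)
    base_canon, base_refl = canonical_flag(K[: op.start] + K[op.end :])
    ins = op.insert
    if base_refl:
        ins = len(base_canon) - ins
        cut, refl = find_circular_cut(cc, reflect(seg))
    return [
        DCJ("excise", chrom_a=K, pos_a=op.start, pos_b=op.end),
        DCJ("reintegrate", chrom_a=base, pos_a=ins, chrom_b=cc, pos_b=cut, reflect_b=refl),
    ]
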