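"""Simulation of ancestor/descendant genome pairs with a known scenario.

Ancestors are built from equal-sized chromosomes that partition the
alphabet, each replicated according to its ploidy.  The descendant is
produced by a random operation sequence of target weight ``w = alpha * n``:
operation kinds are drawn i.i.d. (uniform over the eleven kinds by
default), and given the kind the operation is drawn uniformly from all
valid parameterizations of that kind on the current genome.  Drawing
stops before the accumulated weight would exceed ``w``; since weight-2
kinds exist, the realized weight is ``w`` or ``w - 1`` and is reported as
the true scenario weight.

Four named presets mirror genome sizes typical of yeast (dataset1:
16 chromosomes of ploidy 2, 64 elements), plants (dataset2: 12 of
ploidy 2, 36 elements; dataset3: 5 of ploidy 2, 60 elements) and closely
related *Drosophila* species (dataset4: 5 chromosomes, 200 elements, two
of ploidy 1 and three of ploidy 2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .genome_model import Genome, validate_ancestor
from .operations import Operation, OpKind, WEIGHTS, apply

__all__ = ["SimConfig", "SimInstance", "DATASET_PRESETS", "preset", "make_ancestor", "mutate", "simulate"]


#: the eleven forward operation kinds the generator draws from
FORWARD_KINDS: tuple[OpKind, ...] = (
    OpKind.REVERSAL,
    OpKind.TRANSPOSITION,
    OpKind.INVERTED_TRANSPOSITION,
    OpKind.FUSION,
    OpKind.FISSION,
    OpKind.TRANSLOCATION,
    OpKind.TANDEM_DUPLICATION,
    OpKind.TRANSPOSITION_DUPLICATION,
    OpKind.DELETION,
    OpKind.CHROMOSOME_DUPLICATION,
    OpKind.CHROMOSOME_DELETION,
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; ``w = alpha * n`` is the target scenario weight."""

    n: int
    c: int
    ploidies: tuple[int, ...]
    alpha: float = 0.5
    seed: int = 0
    op_probs: tuple[float, ...] | None = None  # aligned with FORWARD_KINDS
    allow_extinction: bool = True

    def __post_init__(self):
        if self.n % self.c != 0:
            raise ValueError(f"c={self.c} must divide n={self.n}")
        if len(self.ploidies) != self.c:
            raise ValueError("one ploidy per distinct chromosome required")
        if self.op_probs is not None and len(self.op_probs) != len(FORWARD_KINDS):
            raise ValueError("op_probs must match the eleven operation kinds")

    @property
    def target_weight(self) -> int:
        return int(round(self.alpha * self.n))


DATASET_PRESETS: dict[str, SimConfig] = {
    "dataset1": SimConfig(n=64, c=16, ploidies=(2,) * 16),
    "dataset2": SimConfig(n=36, c=12, ploidies=(2,) * 12),
    "dataset3": SimConfig(n=60, c=5, ploidies=(2,) * 5),
    "dataset4": SimConfig(n=200, c=5, ploidies=(1, 1, 2, 2, 2)),
}


def preset(name: str, **overrides) -> SimConfig:
    """A named dataset preset, optionally with fields overridden."""
    try:
        cfg = DATASET_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(DATASET_PRESETS)}") from None
    return replace(cfg, **overrides) if overrides else cfg


def make_ancestor(cfg: SimConfig) -> Genome:
    """Equal-sized chromosomes partitioning ``1..n``, replicated per ploidy."""
    size = cfg.n // cfg.c
    chroms = []
    for i, ploidy in enumerate(cfg.ploidies):
        chrom = tuple(range(i * size + 1, (i + 1) * size + 1))
        chroms.extend([chrom] * ploidy)
    g = Genome(chroms, n=cfg.n)
    validate_ancestor(g).raise_for_violations()
    return g


# ---------------------------------------------------------------------------
# uniform parameter sampling per operation kind

def _intervals(m: int) -> int:
    return m * (m + 1) // 2


def _pick_interval(rng, m: int) -> tuple[int, int]:
    idx = int(rng.integers(_intervals(m)))
    for s in range(m):
        span = m - s
        if idx < span:
            return s, s + idx + 1
        idx -= span
    raise AssertionError


def _pick_copy(rng, g: Genome, weights) -> tuple | None:
    """Choose a chromosome copy with per-copy weight ``weights(K)``."""
    keys = list(g.counts)
    w = np.array([g.counts[k] * weights(k) for k in keys], dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    return keys[int(rng.choice(len(keys), p=w / total))]


def _sample_params(kind: OpKind, g: Genome, rng, cfg: SimConfig) -> Operation | None:
    counts = g.counts
    total_copies = len(g.chromosomes)

    if kind is OpKind.REVERSAL:
        K = _pick_copy(rng, g, lambda k: _intervals(len(k)))
        s, e = _pick_interval(rng, len(K))
        return Operation(kind, chrom=K, start=s, end=e)

    if kind in (OpKind.TRANSPOSITION, OpKind.INVERTED_TRANSPOSITION):
        inv = kind is OpKind.INVERTED_TRANSPOSITION

        def wfun(k):
            m = len(k)
            return sum((m - L + 1) * (m - L + (1 if inv else 0)) for L in range(1, m))

        K = _pick_copy(rng, g, wfun)
        if K is None:
            return None
        m = len(K)
        pairs, weights = [], []
        for s in range(m):
            for e in range(s + 1, m + 1):
                L = e - s
                if L == m:
                    continue
                nins = (m - L + 1) if inv else (m - L)
                if nins > 0:
                    pairs.append((s, e))
                    weights.append(nins)
        w = np.array(weights, dtype=float)
        s, e = pairs[int(rng.choice(len(pairs), p=w / w.sum()))]
        L = e - s
        options = [p for p in range(m - L + 1) if inv or p != s]
        ins = options[int(rng.integers(len(options)))]
        return Operation(kind, chrom=K, start=s, end=e, insert=ins)

    if kind is OpKind.FUSION:
        if total_copies < 2:
            return None
        i, j = rng.choice(total_copies, size=2, replace=False)
        Ka, Kb = g.chromosomes[int(i)], g.chromosomes[int(j)]
        return Operation(kind, chrom=Ka, chrom_b=Kb,
                         reflect_a=bool(rng.integers(2)), reflect_b=bool(rng.integers(2)))

    if kind is OpKind.FISSION:
        K = _pick_copy(rng, g, lambda k: max(len(k) - 1, 0))
        if K is None:
            return None
        return Operation(kind, chrom=K, pos=int(rng.integers(1, len(K))))

    if kind is OpKind.TRANSLOCATION:
        if total_copies < 2:
            return None
        for _ in range(20):
            i, j = rng.choice(total_copies, size=2, replace=False)
            Ka, Kb = g.chromosomes[int(i)], g.chromosomes[int(j)]
            pa = int(rng.integers(len(Ka) + 1))
            pb = int(rng.integers(len(Kb) + 1))
            ra, rb = bool(rng.integers(2)), bool(rng.integers(2))
            if (pa == 0 and pb == len(Kb)) or (pa == len(Ka) and pb == 0):
                continue  # a result would be empty
            return Operation(kind, chrom=Ka, chrom_b=Kb, pos=pa, pos_b=pb,
                             reflect_a=ra, reflect_b=rb)
        return None

    if kind is OpKind.TANDEM_DUPLICATION:
        K = _pick_copy(rng, g, lambda k: _intervals(len(k)))
        s, e = _pick_interval(rng, len(K))
        return Operation(kind, chrom=K, start=s, end=e)

    if kind is OpKind.TRANSPOSITION_DUPLICATION:
        K = _pick_copy(rng, g, lambda k: _intervals(len(k)) if len(k) > 1 else 0)
        if K is None:
            return None
        m = len(K)
        for _ in range(20):
            s, e = _pick_interval(rng, m)
            if e - s == m:
                continue
            d = int(rng.integers(total_copies))
            Kd = g.chromosomes[d]
            ins = int(rng.integers(len(Kd) + 1))
            return Operation(kind, chrom=K, start=s, end=e, chrom_b=Kd, insert=ins)
        return None

    if kind is OpKind.DELETION:
        for _ in range(20):
            K = _pick_copy(rng, g, lambda k: _intervals(len(k)))
            s, e = _pick_interval(rng, len(K))
            if e - s == len(K) and total_copies == 1:
                continue  # would empty the genome
            if not cfg.allow_extinction:
                mult = Counter(abs(x) for ch in g.chromosomes for x in ch)
                mult.subtract(abs(x) for x in K[s:e])
                if any(mult[abs(x)] == 0 for x in K[s:e]):
                    continue
            return Operation(kind, chrom=K, start=s, end=e)
        return None

    if kind is OpKind.CHROMOSOME_DUPLICATION:
        K = g.chromosomes[int(rng.integers(total_copies))]
        return Operation(kind, chrom=K)

    if kind is OpKind.CHROMOSOME_DELETION:
        if total_copies < 2:
            return None
        for _ in range(20):
            K = g.chromosomes[int(rng.integers(total_copies))]
            if not cfg.allow_extinction:
                mult = Counter(abs(x) for ch in g.chromosomes for x in ch)
                mult.subtract(abs(x) for x in K)
                if any(mult[abs(x)] == 0 for x in K):
                    continue
            return Operation(kind, chrom=K)
        return None

    raise ValueError(f"not a forward kind: {kind}")


@dataclass(frozen=True)
class SimInstance:
    """One simulated test case with its generating scenario."""

    config: SimConfig
    rho: Genome
    pi: Genome
    operations: tuple[Operation, ...]
    true_weight: int


def mutate(rho: Genome, cfg: SimConfig, rng=None) -> SimInstance:
    """Apply a random operation sequence of weight close to ``alpha * n``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    w_target = cfg.target_weight
    probs = None
    if cfg.op_probs is not None:
        p = np.array(cfg.op_probs, dtype=float)
        probs = p / p.sum()
    g = rho
    ops: list[Operation] = []
    weight = 0
    misses = 0
    while True:
        k = int(rng.choice(len(FORWARD_KINDS), p=probs))
        kind = FORWARD_KINDS[k]
        w_op = WEIGHTS.get(kind, 1)
        if weight + w_op > w_target:
            break
        op = _sample_params(kind, g, rng, cfg)
        if op is None:
            misses += 1
            if misses > 200:  # no kind applicable; degenerate genome
                break
            continue
        misses = 0
        g = apply(op, g)
        ops.append(op)
        weight += w_op
    return SimInstance(cfg, rho, g, tuple(ops), weight)


def simulate(cfg: SimConfig) -> SimInstance:
    """Build the ancestor and mutate it according to ``cfg``."""
    return mutate(make_ancestor(cfg), cfg)
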