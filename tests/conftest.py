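"""Shared fixtures: random valid ancestors and simulated genome pairs."""

from __future__ import annotations

import numpy as np
import pytest

from dupsort.genome_model import Genome, validate_ancestor
from dupsort.simulator import SimConfig, mutate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_ancestor(rng, max_n: int = 12, max_chroms: int = 4, max_ploidy: int = 2) -> Genome:
    """A random genome satisfying the disjoint-or-identical constraint:
    the alphabet is partitioned into chromosomes, with random orientations
    and random ploidies."""
    n = int(rng.integers(2, max_n + 1))
    ids = list(rng.permutation(np.arange(1, n + 1)))
    k = int(rng.integers(1, min(max_chroms, n) + 1))
    cut_points = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False)) if k > 1 else []
    bounds = [0, *map(int, cut_points), n]
    chroms = []
    for i in range(k):
        part = [int(x) * (1 if rng.random() < 0.5 else -1) for x in ids[bounds[i]: bounds[i + 1]]]
        ploidy = int(rng.integers(1, max_ploidy + 1))
        chroms.extend([tuple(part)] * ploidy)
    g = Genome(chroms, n=n)
    assert validate_ancestor(g).ok
    return g


def random_pair(rng, alpha: float = 0.4, max_n: int = 12):
    """A random ancestor plus a mutated descendant with known weight."""
    rho = random_ancestor(rng, max_n=max_n)
    cfg = SimConfig(n=rho.n, c=1, ploidies=(1,), alpha=alpha, seed=0)
    inst = mutate(rho, cfg, rng=rng)
    return rho, inst.pi, inst.true_weight


@pytest.fixture
def small_pairs(rng):
    return [random_pair(rng) for _ in range(25)]
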