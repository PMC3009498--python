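"""The greedy sorter: candidates, scores, fallback, and end-to-end runs."""

import pytest

from dupsort.genome_model import AncestorConstraintError, Genome
from dupsort.metrics import lower_bound
from dupsort.operations import OpKind, apply
from dupsort.oracle import exact_distance
from dupsort.simulator import SimConfig, preset, simulate
from dupsort.sorter import (
    SorterConfig,
    candidate_lb_ops,
    candidate_tau_ops,
    fallback,
    sort,
)
from conftest import random_ancestor, random_pair


def _assert_replays(rho, pi, scenario):
    n = max(rho.n, pi.n)
    assert scenario.replay(Genome(rho.chromosomes, n=n)) == Genome(pi.chromosomes, n=n)
    assert scenario.total_weight == sum(op.weight for op in scenario.operations)


class TestCandidates:
    def test_identity_has_no_candidates(self):
        g = Genome([(1, 2, 3)])
        assert candidate_lb_ops(g, g) == []
        assert candidate_tau_ops(g, g) == []

    def test_inverse_reversal_decreases_lower_bound(self):
        rho, pi = Genome([(1, 2)]), Genome([(1, -2)], n=2)
        cands = candidate_lb_ops(rho, pi)
        assert cands, "expected a lower-bound-decreasing inverse operation"
        op, score = cands[0]
        assert score[0] >= 1
        assert apply(op, pi) == rho

    def test_fission_between_two_ancestor_telomeres_scores_one_two(self):
        # an inner breakpoint flanked by two ancestor telomeres: splitting
        # there trades two incorrect telomeres for two telomere adjacencies
        rho = Genome([(1,), (2,)])
        pi = Genome([(1, 2)], n=2)
        cands = dict(candidate_lb_ops(rho, pi))
        fission = next(op for op in cands if op.kind is OpKind.FISSION)
        assert cands[fission] == (1, 2)

    def test_inverse_tandem_duplication_candidate(self):
        rho = Genome([(1, 2, 3)])
        pi = Genome([(1, 2, 1, 2, 3)], n=3)
        cands = candidate_tau_ops(rho, pi)
        removals = [op for op, score in cands
                    if op.kind is OpKind.DELETION and score[1] > 0]
        assert removals
        assert any(apply(op, pi) == rho for op in removals)

    def test_inverse_chromosome_duplication_candidate(self):
        rho = Genome([(1, 2, 3)])
        pi = Genome([(1, 2, 3), (1, 2, 3)], n=3)
        all_cands = candidate_lb_ops(rho, pi) + candidate_tau_ops(rho, pi)
        assert any(op.kind is OpKind.CHROMOSOME_DELETION for op, _ in all_cands)

    def test_inverse_deletion_candidate(self):
        rho = Genome([(1, 2, 3)])
        pi = Genome([(1, 3)], n=3)
        all_cands = candidate_lb_ops(rho, pi) + candidate_tau_ops(rho, pi)
        inserts = [op for op, score in all_cands if op.kind is OpKind.INSERTION]
        assert any(apply(op, pi) == rho for op in inserts)


class TestSort:
    def test_identity_yields_empty_scenario(self):
        g = Genome([(1, 2, 3), (4, 5)])
        scenario = sort(g, g)
        assert scenario.operations == ()
        assert scenario.total_weight == 0

    def test_invalid_ancestor_rejected_before_work(self):
        with pytest.raises(AncestorConstraintError):
            sort(Genome([(1, 2), (2, 3)]), Genome([(1, 2, 3)]))

    def test_single_reversal_recovered_at_weight_one(self, rng):
        from dupsort.simulator import _sample_params

        cfg = SimConfig(n=8, c=1, ploidies=(1,), alpha=0.0, seed=0)
        done = 0
        while done < 25:
            rho = random_ancestor(rng, max_n=8)
            op = _sample_params(OpKind.REVERSAL, rho, rng, cfg)
            pi = apply(op, rho)
            if pi == rho:
                continue
            scenario = sort(rho, pi)
            assert scenario.total_weight == 1
            _assert_replays(rho, pi, scenario)
            done += 1

    def test_simulated_instances_replay_exactly(self, rng):
        for seed in range(6):
            inst = simulate(preset("dataset2", alpha=0.4, seed=seed))
            scenario = sort(inst.rho, inst.pi)
            _assert_replays(inst.rho, inst.pi, scenario)
            assert scenario.total_weight >= lower_bound(inst.rho, inst.pi)

    def test_random_ancestor_stress(self, rng):
        for _ in range(25):
            rho, pi, w = random_pair(rng, alpha=0.6)
            scenario = sort(rho, pi)
            _assert_replays(rho, pi, scenario)
            assert scenario.total_weight >= lower_bound(rho, pi)

    def test_potential_decreases_lexicographically(self, rng):
        """Outside the fallback, every accepted step lowers (lb, tau)."""
        inst = simulate(preset("dataset2", alpha=0.5, seed=3))
        scenario = sort(inst.rho, inst.pi)
        prev = None
        for rec in scenario.trace:
            if not rec.phase.startswith("main"):
                continue
            cur = (rec.lb_after, rec.tau_after)
            if prev is not None:
                assert cur < prev
            prev = cur

    def test_oracle_sandwich_on_tiny_instances(self, rng):
        checked = 0
        for _ in range(12):
            rho, pi, _ = random_pair(rng, alpha=0.5, max_n=4)
            scenario = sort(rho, pi)
            _assert_replays(rho, pi, scenario)
            d = exact_distance(rho, pi, max_weight=4)
            if d is None:
                continue
            assert lower_bound(rho, pi) <= d <= scenario.total_weight
            checked += 1
        assert checked >= 4


class TestFallback:
    def test_ploidy_rescaling_round_trip(self):
        rho = Genome([(1, 2)])
        pi = Genome([(1, 2), (1, 2)], n=2)
        scenario = fallback(rho, pi)
        _assert_replays(rho, pi, scenario)
        assert scenario.fallback_used

    def test_missing_content_is_reinserted(self):
        rho = Genome([(1, 2, 3, 4)])
        pi = Genome([(1, 4)], n=4)
        scenario = fallback(rho, pi)
        _assert_replays(rho, pi, scenario)

    def test_content_preserving_finish(self):
        # equal multiplicities but scrambled order: the fallback must
        # finish using only content-preserving operations
        rho = Genome([(1, 2, 3, 4)])
        pi = Genome([(3, 1), (-4, 2)], n=4)
        scenario = fallback(rho, pi)
        _assert_replays(rho, pi, scenario)
        kinds = {op.kind for op in scenario.operations}
        assert OpKind.DELETION not in kinds and OpKind.TANDEM_DUPLICATION not in kinds

    def test_sort_recovers_from_forced_fallback(self, rng):
        # with a tiny step cap the main loop hands over almost at once
        cfg = SorterConfig(max_steps=1)
        for _ in range(10):
            rho, pi, _ = random_pair(rng, alpha=0.5)
            scenario = sort(rho, pi, cfg)
            _assert_replays(rho, pi, scenario)
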