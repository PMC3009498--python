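"""Operation application, inversion round trips, and DCJ equivalence."""

import pytest

from dupsort.genome_model import Genome, multiplicity_table
from dupsort.operations import (
    DCJ,
    Operation,
    OperationError,
    OpKind,
    apply,
    apply_dcj,
    apply_dcj_sequence,
    dcjs_for_transposition,
    invert,
)
from dupsort.simulator import FORWARD_KINDS, SimConfig, _sample_params
from conftest import random_ancestor


class TestApply:
    def test_reversal_single_element_flips_sign(self):
        g = apply(Operation(OpKind.REVERSAL, chrom=(1, 2, 3), start=1, end=2), Genome([(1, 2, 3)]))
        assert g.chromosomes == ((1, -2, 3),)

    def test_tandem_duplication_copies_immediately_after(self):
        g = apply(Operation(OpKind.TANDEM_DUPLICATION, chrom=(1, 2, 3), start=0, end=2),
                  Genome([(1, 2, 3)]))
        assert g.chromosomes == ((1, 2, 1, 2, 3),)

    def test_translocation_swaps_suffixes(self):
        g = apply(Operation(OpKind.TRANSLOCATION, chrom=(1, 2), chrom_b=(3, 4), pos=1, pos_b=1),
                  Genome([(1, 2), (3, 4)]))
        assert g == Genome([(1, 4), (3, 2)], n=4)

    def test_fission_inside_only(self):
        with pytest.raises(OperationError):
            apply(Operation(OpKind.FISSION, chrom=(1, 2), pos=0), Genome([(1, 2)]))
        with pytest.raises(OperationError):
            apply(Operation(OpKind.FISSION, chrom=(1, 2), pos=2), Genome([(1, 2)]))

    def test_transposition_rejects_identity_reinsertion(self):
        with pytest.raises(OperationError):
            apply(Operation(OpKind.TRANSPOSITION, chrom=(1, 2, 3), start=1, end=2, insert=1),
                  Genome([(1, 2, 3)]))

    def test_out_of_range_positions(self):
        with pytest.raises(OperationError):
            apply(Operation(OpKind.REVERSAL, chrom=(1, 2), start=1, end=3), Genome([(1, 2)]))

    def test_deletion_of_whole_chromosome_removes_it(self):
        g = apply(Operation(OpKind.DELETION, chrom=(3, 4), start=0, end=2),
                  Genome([(1, 2), (3, 4)]))
        assert g.chromosomes == ((1, 2),)


class TestInvert:
    def test_reversal_is_self_inverse(self):
        g = Genome([(1, 2, 3)])
        op = Operation(OpKind.REVERSAL, chrom=(1, 2, 3), start=1, end=2)
        inv = invert(op, g)
        assert inv.kind is OpKind.REVERSAL
        assert apply(inv, apply(op, g)) == g

    def test_tandem_duplication_inverts_to_deletion(self):
        g = Genome([(1, 2, 3)])
        op = Operation(OpKind.TANDEM_DUPLICATION, chrom=(1, 2, 3), start=0, end=2)
        inv = invert(op, g)
        assert inv.kind is OpKind.DELETION
        assert apply(inv, apply(op, g)) == g

    def test_weights_preserved_by_kind_mapping(self):
        g = Genome([(1, 2, 3, 4)])
        op = Operation(OpKind.TRANSPOSITION, chrom=(1, 2, 3, 4), start=1, end=2, insert=0)
        assert invert(op, g).weight == op.weight == 2

    @pytest.mark.parametrize("kind", FORWARD_KINDS, ids=lambda k: k.value)
    def test_round_trip_random(self, kind, rng):
        """apply(invert(op, g), apply(op, g)) == g for random genomes."""
        cfg = SimConfig(n=8, c=1, ploidies=(1,), alpha=0.0, seed=0)
        done = 0
        attempts = 0
        while done < 60 and attempts < 600:
            attempts += 1
            g = random_ancestor(rng, max_n=8, max_chroms=3)
            op = _sample_params(kind, g, rng, cfg)
            if op is None:
                continue
            try:
                g2 = apply(op, g)
            except OperationError:
                continue
            assert apply(invert(op, g), g2) == g, f"{kind} {op}"
            done += 1
        assert done >= 30, f"too few applicable samples for {kind}"

    def test_content_effects_by_kind(self, rng):
        """Content-preserving kinds keep every multiplicity; duplications
        raise exactly the copied ids; deletions lower the removed ids."""
        preserving = {OpKind.REVERSAL, OpKind.TRANSPOSITION, OpKind.INVERTED_TRANSPOSITION,
                      OpKind.FUSION, OpKind.FISSION, OpKind.TRANSLOCATION}
        cfg = SimConfig(n=8, c=1, ploidies=(1,), alpha=0.0, seed=0)
        for kind in FORWARD_KINDS:
            done = 0
            for _ in range(200):
                g = random_ancestor(rng, max_n=8, max_chroms=3)
                op = _sample_params(kind, g, rng, cfg)
                if op is None:
                    continue
                try:
                    g2 = apply(op, g)
                except OperationError:
                    continue
                before, after = multiplicity_table(g), multiplicity_table(g2)
                diff = {x: after[x] - before[x] for x in range(1, g.n + 1)
                        if after[x] != before[x]}
                if kind in preserving:
                    assert not diff
                elif kind in (OpKind.TANDEM_DUPLICATION, OpKind.TRANSPOSITION_DUPLICATION):
                    copied = {abs(e) for e in op.chrom[op.start:op.end]}
                    assert set(diff) == copied and all(d > 0 for d in diff.values())
                elif kind is OpKind.CHROMOSOME_DUPLICATION:
                    assert set(diff) == {abs(e) for e in op.chrom}
                elif kind is OpKind.DELETION:
                    assert all(d < 0 for d in diff.values())
                    assert set(diff) <= {abs(e) for e in op.chrom[op.start:op.end]}
                elif kind is OpKind.CHROMOSOME_DELETION:
                    assert all(d < 0 for d in diff.values())
                done += 1
                if done >= 25:
                    break
            assert done >= 10, f"too few samples for {kind}"


class TestDCJ:
    def test_dcj_realizes_reversal(self):
        g = Genome([(1, 2, 3, 4)])
        d = DCJ("reversal", chrom_a=(1, 2, 3, 4), pos_a=1, pos_b=3)
        assert apply_dcj(d, g).chromosomes == ((1, -3, -2, 4),)
        op = Operation(OpKind.REVERSAL, chrom=(1, 2, 3, 4), start=1, end=3)
        assert apply_dcj(d, g) == apply(op, g)

    def test_end_cut_realizes_fission(self):
        g = Genome([(1, 2, 3)])
        d = DCJ("split", chrom_a=(1, 2, 3), pos_a=1)
        assert apply_dcj(d, g) == apply(Operation(OpKind.FISSION, chrom=(1, 2, 3), pos=1), g)

    def test_join_realizes_fusion_and_translocation(self):
        g = Genome([(1, 2), (3, 4)])
        fusion = DCJ("join", chrom_a=(1, 2), pos_a=2, chrom_b=(3, 4), pos_b=0)
        assert apply_dcj(fusion, g) == apply(
            Operation(OpKind.FUSION, chrom=(1, 2), chrom_b=(3, 4)), g)
        tr = DCJ("join", chrom_a=(1, 2), pos_a=1, chrom_b=(3, 4), pos_b=1)
        assert apply_dcj(tr, g) == apply(
            Operation(OpKind.TRANSLOCATION, chrom=(1, 2), chrom_b=(3, 4), pos=1, pos_b=1), g)

    def test_two_dcjs_realize_transposition(self):
        g = Genome([(1, 2, 3)])
        op = Operation(OpKind.TRANSPOSITION, chrom=(1, 2, 3), start=1, end=2, insert=0)
        seq = dcjs_for_transposition(op, g)
        assert len(seq) == 2
        assert apply_dcj_sequence(seq, g) == apply(op, g) == Genome([(2, 1, 3)])

    def test_random_transpositions_match_two_dcjs(self, rng):
        cfg = SimConfig(n=8, c=1, ploidies=(1,), alpha=0.0, seed=0)
        done = 0
        for _ in range(200):
            g = random_ancestor(rng, max_n=8, max_chroms=2)
            for kind in (OpKind.TRANSPOSITION, OpKind.INVERTED_TRANSPOSITION):
                op = _sample_params(kind, g, rng, cfg)
                if op is None:
                    continue
                try:
                    expected = apply(op, g)
                except OperationError:
                    continue
                assert apply_dcj_sequence(dcjs_for_transposition(op, g), g) == expected
                done += 1
            if done >= 40:
                break
        assert done >= 20

    def test_circular_intermediate_must_resolve(self):
        g = Genome([(1, 2, 3)])
        with pytest.raises(OperationError):
            apply_dcj(DCJ("excise", chrom_a=(1, 2, 3), pos_a=1, pos_b=2), g)
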