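"""Chromosome canonicalization, telomeres, adjacencies, classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupsort.genome_model import (
    AncestorConstraintError,
    Extremity,
    Genome,
    GenomeError,
    adjacencies,
    canonical,
    classify_breakpoints,
    multiplicity,
    reflect,
    telomere_count,
    telomere_table,
    validate_ancestor,
)
from conftest import random_ancestor


def E(text):
    return Extremity.parse(text)


signed_ids = st.integers(min_value=1, max_value=9).flatmap(
    lambda x: st.sampled_from([x, -x]))
chromosomes = st.lists(signed_ids, min_size=1, max_size=8).map(tuple)


class TestChromosomes:
    @settings(derandomize=True, max_examples=200)
    @given(chromosomes)
    def test_canonicalization_properties(self, c):
        assert reflect(reflect(c)) == c
        assert canonical(canonical(c)) == canonical(c)
        assert canonical(c) == canonical(reflect(c))
        assert canonical(c) in (c, reflect(c))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(chromosomes, min_size=1, max_size=4))
    def test_genome_invariants(self, chroms):
        g = Genome(chroms)
        assert sum(telomere_table(g)) == 2 * len(g.chromosomes)
        assert sum(adjacencies(g).values()) == sum(len(c) - 1 for c in g.chromosomes)
        # reflection of any input chromosome leaves the genome unchanged
        assert Genome([reflect(chroms[0])] + list(chroms[1:])) == g

    def test_reflection_is_involution_and_canonical_idempotent(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 8))
            c = tuple(int(x) * (1 if rng.random() < 0.5 else -1)
                      for x in rng.integers(1, 10, size=m))
            assert reflect(reflect(c)) == c
            assert canonical(canonical(c)) == canonical(c)
            assert canonical(c) == canonical(reflect(c))

    def test_equality_modulo_reflection(self):
        assert Genome([(1, 2)]) == Genome([(-2, -1)])
        assert Genome([(1, -2, 3)]) == Genome([(-3, 2, -1)])

    def test_empty_chromosome_rejected(self):
        with pytest.raises(GenomeError):
            Genome([()])

    def test_zero_id_rejected(self):
        with pytest.raises(GenomeError):
            Genome([(1, 0)])

    def test_id_above_alphabet_rejected(self):
        with pytest.raises(GenomeError):
            Genome([(1, 5)], n=3)


class TestMultiplicity:
    @pytest.mark.parametrize(
        "chroms, x, expected",
        [
            ([(1, 2)], 1, 1),
            ([(1, -1, 2)], 1, 2),  # orientation is ignored
            ([(1, 2), (1, 2)], 2, 2),  # multiset copies both count
        ],
    )
    def test_counts(self, chroms, x, expected):
        assert multiplicity(Genome(chroms), x) == expected

    def test_out_of_range(self):
        with pytest.raises(GenomeError):
            multiplicity(Genome([(1, 2)]), 3)


class TestTelomeres:
    @pytest.mark.parametrize(
        "chroms, ext, expected",
        [
            ([(1, 2)], "1t", 1),
            ([(1, 2)], "1h", 0),  # interior extremity
            ([(-2, -1)], "1t", 1),  # reflection equivalent of (1 2)
        ],
    )
    def test_counts(self, chroms, ext, expected):
        assert telomere_count(Genome(chroms, n=2), E(ext)) == expected

    def test_total_is_twice_chromosome_count(self, rng):
        for _ in range(50):
            g = random_ancestor(rng)
            assert sum(telomere_table(g)) == 2 * len(g.chromosomes)


class TestAdjacencies:
    def test_single_junction(self):
        assert dict(adjacencies(Genome([(1, 2)]))) == {(E("1h"), E("2t")): 1}

    def test_single_element_has_none(self):
        assert not adjacencies(Genome([(1,)]))

    def test_negative_orientation(self):
        # (1 -2) reads 1t 1h 2h 2t, so the junction pairs head with head
        assert dict(adjacencies(Genome([(1, -2)], n=2))) == {(E("1h"), E("2h")): 1}


class TestClassification:
    def test_telomere_adjacencies_and_breakpoints(self):
        # descendant splits (1 2 3): 1t and 3h remain valid telomeres,
        # the new end 2h does not exist as an ancestor telomere
        rho = Genome([(1, 2, 3)])
        pi = Genome([(1, 2), (1, 3)], n=3)
        cls = classify_breakpoints(rho, pi)
        assert sorted(map(str, cls.telomere_adjacencies)) == ["1t", "1t", "3h"]
        assert sorted(map(str, cls.telomere_breakpoints)) == ["2h"]

    def test_identity_has_no_breakpoints(self, rng):
        for _ in range(30):
            g = random_ancestor(rng)
            cls = classify_breakpoints(g, g)
            assert not cls.inner_breakpoints
            assert not cls.telomere_breakpoints

    def test_swapped_order_is_all_breakpoints(self):
        rho = Genome([(1, 2)])
        pi = Genome([(2, 1)], n=2)
        cls = classify_breakpoints(rho, pi)
        assert len(cls.inner_breakpoints) == 1
        assert not cls.inner_adjacencies
        assert sorted(map(str, cls.telomere_breakpoints)) == ["1h", "2t"]


class TestAncestorValidation:
    def test_disjoint_ok(self):
        assert validate_ancestor(Genome([(1, 2), (3, 4)])).ok

    def test_identical_copies_ok(self):
        assert validate_ancestor(Genome([(1, 2), (1, 2)])).ok

    def test_overlap_reported(self):
        report = validate_ancestor(Genome([(1, 2), (2, 3)]))
        assert not report.ok
        assert "2" in report.violations[0]
        with pytest.raises(AncestorConstraintError):
            report.raise_for_violations()

    def test_missing_element_reported(self):
        report = validate_ancestor(Genome([(1, 2)], n=3))
        assert not report.ok
        assert any("3" in v for v in report.violations)
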