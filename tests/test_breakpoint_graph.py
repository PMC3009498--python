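"""Breakpoint graph construction, components, loops, and bridges.

Bridge detection is cross-checked against a brute-force oracle built on
networkx: remove one multiset copy of each black edge (or pair) and
compare connected-component counts.
"""

import itertools
from collections import Counter

import networkx as nx
import pytest

from dupsort.breakpoint_graph import build
from dupsort.genome_model import Extremity, Genome, ext_id
from conftest import random_ancestor, random_pair


def pair(a, b):
    u = ext_id(*_parse(a))
    v = ext_id(*_parse(b))
    return (u, v) if u <= v else (v, u)


def _parse(text):
    e = Extremity.parse(text)
    return e.element, e.head


class TestBuild:
    def test_identity_graph(self):
        g = build(Genome([(1, 2, 3)]), Genome([(1, 2, 3)]))
        expected = {pair("1h", "2t"), pair("2h", "3t")}
        assert set(g.gray) == expected
        assert set(g.black) == expected
        # components: {1t}, {1h,2t}, {2h,3t}, {3h}
        assert g.count_components() == 4

    def test_black_edges_suppressed_at_ancestor_telomeres(self):
        g = build(Genome([(1, 2)]), Genome([(1,), (2,)], n=2))
        assert set(g.gray) == {pair("1h", "2t")}
        assert not g.black
        assert g.count_components() == 3

    def test_joining_two_ancestor_chromosomes_adds_no_black_edge(self):
        # the junction (3h, 4t) touches ancestor telomeres only
        g = build(Genome([(1, 2, 3), (4, 5, 6)]), Genome([(1, 2, 3, 4, 5, 6)], n=6))
        assert pair("3h", "4t") not in g.black

    def test_black_multiplicity(self):
        g = build(Genome([(1, 2)]), Genome([(1, 2), (1, 2)], n=2))
        assert g.black[pair("1h", "2t")] == 2

    def test_invalid_ancestor_rejected(self):
        from dupsort.genome_model import AncestorConstraintError
        with pytest.raises(AncestorConstraintError):
            build(Genome([(1, 2), (2, 3)]), Genome([(1, 2, 3)]))


class TestComponentsAndLoops:
    def test_self_components_formula(self, rng):
        # C(rho, rho) = n + number of distinct chromosomes
        for _ in range(100):
            g = random_ancestor(rng)
            bg = build(g, g)
            assert bg.count_components() == g.n + len(g.counts)
            assert bg.count_loops() == 0

    def test_loop_from_element_followed_by_its_inverse(self):
        bg = build(Genome([(1, 2, 3)]), Genome([(1, 2, -2, 3)], n=3))
        assert bg.count_loops() == 1
        assert bg.loop_vertices() == [ext_id(2, True)]
        assert bg.loops_per_component() == [1]

    def test_no_loop_without_inverse_repeat(self):
        bg = build(Genome([(1, 2)]), Genome([(1, -2)], n=2))
        assert bg.count_loops() == 0


def _nx_components(bg, drop=None):
    g = nx.MultiGraph()
    g.add_nodes_from(range(2 * bg.n))
    for u, v in bg.gray:
        g.add_edge(u, v)
    black = Counter(bg.black)
    if drop:
        black.subtract(drop)
    for (u, v), mult in black.items():
        for _ in range(mult):
            g.add_edge(u, v)
    return nx.number_connected_components(g)


def _brute_force_bridges(bg):
    base = _nx_components(bg)
    ones = [e for e in bg.black if e[0] != e[1]
            and _nx_components(bg, Counter({e: 1})) > base]
    one_set = set(ones)
    twos = []
    cands = [e for e in bg.black if e[0] != e[1] and e not in one_set]
    for e1, e2 in itertools.combinations_with_replacement(cands, 2):
        drop = Counter([e1, e2])
        if any(bg.black[e] < c for e, c in drop.items()):
            continue
        if _nx_components(bg, drop) > base:
            twos.append((e1, e2) if e1 <= e2 else (e2, e1))
    return sorted(ones), sorted(set(twos))


class TestBridges:
    def test_structural_one_bridge(self):
        # a lone black edge joining two otherwise-disconnected gray paths:
        # (-2 -3) realizes the junction (2t, 3h) between the gray
        # components of (1 2) and (3 4)
        bg = build(Genome([(1, 2), (3, 4)]), Genome([(1,), (4,), (-2, -3)], n=4))
        assert bg.one_bridge_edges() == [pair("2t", "3h")]
        assert bg.count_components() == 5

    def test_multiplicity_two_edge_is_never_a_one_bridge(self):
        bg = build(Genome([(1, 2, 3)]), Genome([(1, 3), (1, 3)], n=3))
        assert bg.black[pair("1h", "3t")] == 2
        assert bg.one_bridge_edges() == []

    def test_double_edge_can_be_a_two_bridge_with_itself(self):
        # both copies of (1h, 3t) must go to split the component
        bg = build(Genome([(1, 2, 3)]), Genome([(1, 3), (1, 3)], n=3))
        e = pair("1h", "3t")
        assert (e, e) in bg.two_bridge_edges()

    def test_brute_force_equivalence(self, rng):
        checked = 0
        for _ in range(60):
            rho, pi, _ = random_pair(rng, alpha=0.5, max_n=6)
            bg = build(rho, pi, check=False)
            ones_bf, twos_bf = _brute_force_bridges(bg)
            assert bg.one_bridge_edges() == ones_bf
            assert sorted(bg.two_bridge_edges()) == twos_bf
            checked += 1
        assert checked == 60

    def test_removing_a_bridge_increases_components_by_one(self, rng):
        for _ in range(40):
            rho, pi, _ = random_pair(rng, alpha=0.4, max_n=6)
            bg = build(rho, pi, check=False)
            base = _nx_components(bg)
            for e in bg.one_bridge_edges():
                assert _nx_components(bg, Counter({e: 1})) == base + 1
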