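"""Supernatural graph construction, decomposition and component census."""

import pytest

from dcjhalving.genome_model import Homology, Matching
from dcjhalving.simulator import make_fixture
from dcjhalving.sng import (
    PseudoCap,
    add_pseudo_caps,
    build_sng,
    census_of,
    classify_components,
    decompose,
    to_dot,
)

from .conftest import genome, resolved_matching


class TestBuild:
    def test_resolved_pair_gives_two_extremity_edges(self):
        g = genome("c:1 2 1")
        sng = build_sng(g, Homology.of(g))
        assert len(sng.vertices) == 6
        assert len(sng.adjacency_edges) == 3
        assert len(sng.extremity_edges) == 2

    def test_all_singular_genome_has_no_extremity_edges(self):
        g = genome("l:1 2 3")
        sng = build_sng(g, Homology.of(g))
        assert sng.extremity_edges == []

    def test_family_of_three_gives_complete_graph(self):
        g = genome("l:a a a")
        sng = build_sng(g, Homology.of(g))
        assert len(sng.extremity_edges) == 6  # 3 tail-tail + 3 head-head

    def test_dot_export_mentions_both_edge_kinds(self):
        g = genome("c:1 2 1")
        dot = to_dot(build_sng(g, Homology.of(g)))
        assert "kind=adjacency" in dot and "kind=extremity" in dot


class TestPseudoCaps:
    def test_one_cap_per_telomere(self):
        g = genome("l:1 2; l:3")
        sng = add_pseudo_caps(build_sng(g, Homology.of(g)))
        caps = [v for v in sng.vertices if isinstance(v, PseudoCap)]
        assert len(caps) == 4

    def test_all_circular_genome_unchanged(self):
        g = genome("c:1 2")
        sng = build_sng(g, Homology.of(g))
        assert add_pseudo_caps(sng) is sng

    def test_every_vertex_gets_exactly_one_adjacency_edge(self):
        g = genome("l:1 2 1; c:3")
        sng = add_pseudo_caps(build_sng(g, Homology.of(g)))
        degree = {v: 0 for v in sng.vertices}
        for e in sng.adjacency_edges:
            for v in e:
                degree[v] += 1
        assert set(degree.values()) == {1}

    def test_caps_have_lowest_indices(self):
        g = genome("l:1 2")
        sng = add_pseudo_caps(build_sng(g, Homology.of(g)))
        cap_ix = [sng.vertex_index[v] for v in sng.vertices if isinstance(v, PseudoCap)]
        reg_ix = [sng.vertex_index[v] for v in sng.vertices if not isinstance(v, PseudoCap)]
        assert max(cap_ix) < min(reg_ix)


class TestDecompose:
    def test_resolved_decomposition_keeps_all_edges(self):
        g = genome("c:1 2 1")
        sng = build_sng(g, Homology.of(g))
        simple = decompose(sng, resolved_matching(g))
        assert len(simple.graph.extremity_edges) == len(sng.extremity_edges)

    def test_empty_matching_leaves_only_adjacency_paths(self):
        g = genome("l:1 2")
        sng = build_sng(g, Homology.of(g))
        simple = decompose(sng, Matching(frozenset(), frozenset(g.markers())))
        assert simple.graph.extremity_edges == []
        assert all(not c.is_cycle for c in simple.components)

    def test_partial_matching_in_big_family_leaves_lava(self):
        g = genome("l:a a a")
        h = Homology.of(g)
        fam = h.families["a"]
        m = Matching.from_pairs([frozenset(fam[:2])], fam)
        simple = decompose(build_sng(g, h), m)
        census = classify_components(simple, m)
        assert census.n == 1

    def test_cross_family_pair_rejected(self):
        g = genome("l:1 2")
        with pytest.raises(ValueError):
            Matching(frozenset([frozenset(g.markers())]), frozenset())


class TestCensus:
    def test_even_pontoon_trace(self):
        # circular (1 2 3) with 1=3: path t2-h1-h3-t1-t3-h2, two extremity edges
        g = genome("c:1 2 1")
        m = resolved_matching(g)
        census = classify_components(decompose(build_sng(g, Homology.of(g)), m), m)
        assert census.n == 1 and census.p_gg_even == 1
        assert census.c_even == census.c_odd == census.piers == 0

    def test_isolated_telomere_lava_vertices_are_even_piers(self):
        # linear [2 1 3 4] with 1=3: isolated t2 and h4 are even piers
        g = genome("l:2 1 1 4")
        m = resolved_matching(g)
        census = census_of(g, m)
        assert census.n == 1 and census.p_Gg_even == 2 and census.p_gg_even == 1
        assert census.p_Gg_odd == census.p_GG_odd == census.p_gg_odd == 0

    def test_mixed_pier_pontoon_trace(self):
        # linear [1 2 3 4] with 2=4: one even pier, one odd pier, one odd pontoon
        g = genome("l:1 2 3 2")
        m = resolved_matching(g)
        census = census_of(g, m)
        assert (census.p_Gg_even, census.p_Gg_odd, census.p_gg_odd) == (1, 1, 1)

    def test_circular_singletons_removed_before_census(self):
        g = genome("c:1 2 1; c:7 8")
        m = resolved_matching(g)
        census = census_of(g, m)
        assert census.circular_singletons == 1
        assert census.p_gg_even == 1  # only the pontoon of the first chromosome

    @pytest.mark.parametrize("seed", range(12))
    def test_census_invariants_on_random_genomes(self, seed):
        g, h = make_fixture("resolved", 16 + seed, seed=seed)
        m = Matching.from_resolved_homology(h)
        census = census_of(g, m)
        # pier parity: the number of piers is always even
        assert census.piers % 2 == 0
        assert (census.p_Gg_even - census.p_Gg_odd) % 2 == 0
        # odd-component parity: total extremity edges are even
        odd_total = census.c_odd + census.p_GG_odd + census.p_Gg_odd + census.p_gg_odd
        assert odd_total % 2 == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_census_identical_with_and_without_pseudo_caps(self, seed):
        g, h = make_fixture("resolved", 14, seed=100 + seed)
        m = Matching.from_resolved_homology(h)
        bare = build_sng(g, h)
        with_caps = add_pseudo_caps(bare)
        c1 = classify_components(decompose(bare, m), m)
        c2 = classify_components(decompose(with_caps, m), m)
        c3 = census_of(g, m)
        assert c1 == c2 == c3

    def test_component_vertices_partition_the_graph(self):
        g, h = make_fixture("resolved", 20, seed=5)
        m = Matching.from_resolved_homology(h)
        simple = decompose(add_pseudo_caps(build_sng(g, h)), m)
        seen = [v for c in simple.components for v in c.vertices]
        assert len(seen) == len(set(seen)) == len(simple.graph.vertices)
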