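"""Closed-form halving distance and optimal sorting for resolved homologies."""

import numpy as np
import pytest

from dcjhalving.genome_model import Genome, Matching, Operation, apply_operation, is_sd
from dcjhalving.halving_resolved import (
    Scenario,
    UnresolvedHomologyError,
    halving_distance,
    halving_distance_census,
    sort_halving,
    verify_scenario,
)
from dcjhalving.simulator import make_fixture
from dcjhalving.sng import ComponentCensus, census_of

from .conftest import genome, random_dcj, resolved_matching, scramble


class TestDistanceFormula:
    def test_sd_census_gives_zero(self):
        census = ComponentCensus(n=2, c_even=2)
        assert halving_distance_census(census).distance == 0

    @pytest.mark.parametrize(
        "spec, expected",
        [
            ("c:1 2 1", 1),  # delete marker 2 to reach the doubled circle
            ("c:1 2 2 1", 1),  # one DCJ reaches (1 1) + (2 -2)
            ("l:2 1 1 4", 2),  # extract circular (1 1), delete linear [2 4]
            ("l:1 2 3 2", 3),  # delta edge case: 1 + ceil((2+1)/2)
            ("l:1 -1 3", 2),  # odd q: the ceiling rule
        ],
    )
    def test_worked_examples(self, spec, expected):
        assert halving_distance(genome(spec)).distance == expected

    def test_delta_edge_case_terms(self):
        bd = halving_distance(genome("l:1 2 3 2"))
        assert (bd.q, bd.delta) == (2, 1)

    def test_identical_doubled_chromosomes_distance_zero(self):
        g = genome("c:1 2; c:1 2")
        assert halving_distance(g).distance == 0
        assert is_sd(g, resolved_matching(g))

    def test_circular_singletons_add_one_each(self):
        base = genome("c:1 2; c:1 2")
        with_singletons = genome("c:1 2; c:1 2; c:7; c:8 9")
        assert halving_distance(with_singletons).distance == (
            halving_distance(base).distance + 2
        )

    def test_unresolved_homology_is_rejected(self):
        with pytest.raises(UnresolvedHomologyError):
            halving_distance(genome("c:1 1 1"))

    def test_negative_census_count_rejected(self):
        with pytest.raises(ValueError):
            halving_distance_census(ComponentCensus(n=-1))


class TestDistanceProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_sd_iff_distance_zero(self, seed):
        g, h = make_fixture("sd", 4 + 2 * (seed % 12), seed=seed)
        m = resolved_matching(g)
        assert halving_distance(g, h).distance == 0
        assert is_sd(g, m)
        # a random perturbation can raise the distance by at most one
        perturbed = scramble(g, 1, seed)
        d = halving_distance(perturbed).distance
        assert d in (0, 1)
        assert (d == 0) == is_sd(perturbed, resolved_matching(perturbed))

    @pytest.mark.parametrize("seed", range(15))
    def test_single_dcj_changes_distance_by_at_most_one(self, seed):
        g, h = make_fixture("resolved", 18, seed=seed)
        d0 = halving_distance(g, h).distance
        rng = np.random.default_rng(seed)
        for _ in range(10):
            op = random_dcj(g, rng)
            if op is None:
                break
            d1 = halving_distance(apply_operation(g, op)).distance
            assert abs(d1 - d0) <= 1

    @pytest.mark.parametrize("seed", range(15))
    def test_mixtacki_limit_without_singular_markers(self, seed):
        # duplicated genomes, rearranged by DCJs only: no singular markers
        g, _ = make_fixture("sd", 12 + seed, seed=seed)
        g = scramble(g, 3 + seed, seed)
        m = resolved_matching(g)
        assert not m.singular
        census = census_of(g, m)
        mixtacki = census.n - census.c_even - census.p_GG_odd // 2
        assert halving_distance(g).distance == mixtacki


class TestSorting:
    def test_sd_input_gives_empty_scenario(self):
        g = genome("c:1 2; c:1 2")
        assert len(sort_halving(g)) == 0

    def test_single_dcj_scenario(self):
        g = genome("c:1 2 2 1")
        sc = sort_halving(g)
        assert len(sc) == 1 and sc.operations[0].kind == "dcj"
        assert is_sd(sc.final_genome, resolved_matching(g))

    def test_single_deletion_scenario(self):
        g = genome("c:1 2 1")
        sc = sort_halving(g)
        assert len(sc) == 1 and sc.operations[0].kind == "deletion"
        assert [m.family for m in sc.operations[0].segment] == ["2"]

    def test_circular_singletons_sorted_by_deletion(self):
        g = genome("c:1 2; c:1 2; c:9")
        sc = sort_halving(g)
        assert len(sc) == 1 and sc.operations[0].kind == "deletion"

    @pytest.mark.parametrize("seed", range(30))
    def test_scenario_length_equals_formula(self, seed):
        g, h = make_fixture("resolved", 6 + seed, seed=500 + seed)
        sc = sort_halving(g, h)
        assert len(sc) == halving_distance(g, h).distance
        assert verify_scenario(g, sc, resolved_matching(g))


class TestVerifier:
    def test_deleting_matched_marker_rejected(self):
        g = genome("c:1 2 1")
        bad = Scenario(operations=[Operation.deletion([g.markers()[0]])])
        assert not verify_scenario(g, bad, resolved_matching(g))

    def test_truncated_scenario_rejected(self):
        g, h = make_fixture("resolved", 14, seed=77)
        sc = sort_halving(g, h)
        if len(sc) == 0:
            pytest.skip("fixture happened to be SD")
        truncated = Scenario(operations=sc.operations[:-1])
        assert not verify_scenario(g, truncated, resolved_matching(g))

    def test_inapplicable_operation_rejected(self):
        g = genome("l:1 2")
        from dcjhalving.genome_model import Marker, adjacency

        bogus = Operation.dcj([adjacency(Marker("1", 1).tail, Marker("2", 1).tail)], [])
        assert not verify_scenario(g, Scenario(operations=[bogus]), resolved_matching(g))

    def test_legal_insertion_reaching_sd_accepted(self):
        from dcjhalving.genome_model import Marker, adjacency

        # circular (1 2 1): inserting 2's missing homolog between the second 1
        # and the first 1 yields the interleaved doubled circle (1 2 1 2)
        g = genome("c:1 2 1")
        site = adjacency(Marker("1", 2).head, Marker("1", 1).tail)
        ins = Operation.insertion([(Marker("2", 2), 1)], ("adjacency", site))
        assert verify_scenario(g, Scenario(operations=[ins]), resolved_matching(g))

    def test_duplicate_insertion_for_same_singular_rejected(self):
        from dcjhalving.genome_model import Marker

        g = genome("c:1 2 1")
        ops = [
            Operation.insertion([(Marker("2", 2), 1)], None),
            Operation.insertion([(Marker("2", 3), 1)], None),
        ]
        assert not verify_scenario(g, Scenario(operations=ops), resolved_matching(g))
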