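"""Capping-free halving ILP: construction, solving, decoding."""

import math

import pytest

from dcjhalving.genome_model import Homology, Matching, is_sd
from dcjhalving.halving_ilp import (
    SolverUnavailableError,
    build_ilp,
    halve_natural,
    solve_ilp,
    write_lp,
)
from dcjhalving.halving_resolved import halving_distance, verify_scenario
from dcjhalving.oracle import min_over_matchings
from dcjhalving.simulator import make_fixture
from dcjhalving.sng import census_of

from .conftest import genome, resolved_matching


class TestBuild:
    def test_variable_counts_for_tiny_instance(self):
        # circular (1 2 3) with 1=3: 6 vertices, no pseudo-caps, 3 d-variables,
        # one sibling-pair variable covering the two candidate extremity edges
        g = genome("c:1 2 1")
        model = build_ilp(g)
        names = [v[0] for v in model.variables]
        assert sum(n.startswith("d_") for n in names) == 3
        assert len(model.pair_vars) == 1
        assert sum(n.startswith("a_") for n in names) == 6  # no caps added

    def test_maximum_matching_constraint_per_family(self):
        g = genome("c:1 2 1")
        model = build_ilp(g)
        c06 = [c for c in model.constraints if c.tag == "C.06"]
        assert len(c06) == 2  # families {1,1}, {2}
        assert sorted(c.lb for c in c06) == [0, 1]

    def test_model_size_linear_in_markers(self):
        g1, h1 = make_fixture("resolved", 20, seed=3)
        g2, h2 = make_fixture("resolved", 40, seed=3)
        m1, m2 = build_ilp(g1, h1), build_ilp(g2, h2)
        k1 = len(g1.markers()) + len(g1.telomeres())
        k2 = len(g2.markers()) + len(g2.telomeres())
        assert m2.num_variables / m1.num_variables < 1.6 * k2 / k1
        assert m2.num_constraints / m1.num_constraints < 1.6 * k2 / k1

    def test_empty_genome_builds_trivial_model(self):
        from dcjhalving.genome_model import Genome

        model = build_ilp(Genome("E", []))
        assert model.num_variables == 0
        sol = solve_ilp(model)
        assert sol.distance == 0


class TestLPExport:
    def test_deterministic_output(self, tmp_path):
        g, h = make_fixture("natural", 10, seed=9)
        p1, p2 = tmp_path / "a.lp", tmp_path / "b.lp"
        write_lp(build_ilp(g, h), p1)
        write_lp(build_ilp(g, h), p2)
        assert p1.read_text() == p2.read_text()

    def test_sections_present(self, tmp_path):
        g = genome("c:1 2 1")
        path = tmp_path / "m.lp"
        write_lp(build_ilp(g), path)
        text = path.read_text()
        for section in ("Minimize", "Subject To", "Bounds", "Generals", "End"):
            assert section in text


class TestSolve:
    def test_all_singular_circular_chromosome_costs_one(self):
        g = genome("c:1 2 3 4")
        sol = solve_ilp(build_ilp(g))
        assert sol.distance == 1  # one circular singleton deletion
        assert sol.assignment["s"] == pytest.approx(1)

    def test_family_of_three_forces_one_deletion(self):
        g = genome("c:1 2 1 1 3")
        sol = solve_ilp(build_ilp(g))
        d_vals = [v for k, v in sol.assignment.items() if k.startswith("d_1.")]
        assert sum(round(v) for v in d_vals) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_resolved_equivalence_with_closed_form(self, seed):
        g, h = make_fixture("resolved", 12 + 2 * seed, seed=40 + seed)
        sol = solve_ilp(build_ilp(g, h))
        assert sol.distance == halving_distance(g, h).distance

    @pytest.mark.parametrize("seed", range(12))
    def test_natural_equivalence_with_enumeration(self, seed):
        g, h = make_fixture("natural", 9, seed=70 + seed)
        sol = solve_ilp(build_ilp(g, h))
        assert sol.distance == min_over_matchings(g, h)

    @pytest.mark.parametrize("seed", range(8))
    def test_decoded_solution_is_consistent(self, seed):
        g, h = make_fixture("natural", 10, seed=130 + seed)
        sol = solve_ilp(build_ilp(g, h))
        assert sol.matching.is_maximum(h)
        census = census_of(g, sol.matching)
        assert census.piers % 2 == 0
        assert sol.breakdown.distance == sol.distance
        assert math.ceil(sol.objective - 1e-6) == sol.distance

    def test_lp_only_backend_refuses_to_solve(self):
        g = genome("c:1 2 1")
        with pytest.raises(SolverUnavailableError):
            solve_ilp(build_ilp(g), backend="lp-only")


class TestHalveNatural:
    def test_resolved_input_matches_direct_pipeline(self):
        g, h = make_fixture("resolved", 16, seed=11)
        matching, breakdown, scenario = halve_natural(g, h)
        assert breakdown.distance == halving_distance(g, h).distance
        assert len(scenario) == breakdown.distance
        assert verify_scenario(g, scenario, matching)

    def test_doubled_natural_genome_has_distance_zero(self):
        g = genome("c:1 1; c:1 1")  # family of four: SD under some matching
        matching, breakdown, scenario = halve_natural(g)
        assert breakdown.distance == 0 and len(scenario) == 0
        assert is_sd(g, matching)

    @pytest.mark.parametrize("seed", range(6))
    def test_scenario_sorts_natural_genome(self, seed):
        g, h = make_fixture("natural", 10, seed=160 + seed)
        matching, breakdown, scenario = halve_natural(g, h)
        assert len(scenario) == breakdown.distance == min_over_matchings(g, h)
        assert verify_scenario(g, scenario, matching)
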