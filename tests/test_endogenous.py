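"""Model 2 (goal-function) dynamics: weights, payoffs, best response, runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiralsilence import _kernels
from spiralsilence.endogenous_model import (
    best_response,
    expressing_count,
    goal,
    influence_weight,
    run_endogenous,
    time_unit_endogenous,
)
from spiralsilence.fixtures import make_fixture
from spiralsilence.netgen import Graph, assign_population, build_graph, sample_degree_sequence

from tests.conftest import make_population


@pytest.fixture
def worked_example():
    """Node 0 (deg 2, b=+1, sigma=0.5), neighbors: 1 (deg 4, omega=+1),
    2 (deg 2, omega=0)."""
    edges = [(0, 1), (0, 2), (1, 3), (1, 4), (1, 5), (2, 6)]
    g = Graph.from_edges(7, edges)
    pop = make_population(
        b=[1, 1, 1, 1, 1, 1, 1],
        sigma=[0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
        omega=[0, 1, 0, 0, 0, 0, 0],
    )
    return g, pop


class TestInfluenceWeight:
    def test_degree_ratio(self, worked_example):
        g, _ = worked_example
        assert influence_weight(g, 0, 1) == 2.0  # deg 4 / deg 2
        assert influence_weight(g, 1, 0) == 0.5
        assert influence_weight(g, 0, 2) == 1.0

    def test_reciprocal_product_is_one(self, worked_example):
        g, _ = worked_example
        assert influence_weight(g, 0, 1) * influence_weight(g, 1, 0) == 1.0

    def test_non_neighbor_raises(self, worked_example):
        g, _ = worked_example
        with pytest.raises(ValueError):
            influence_weight(g, 0, 3)


class TestExpressingCount:
    def test_counts_non_silent_neighbors(self, triangle_graph):
        pop = make_population(b=[1, 1, -1], sigma=[0.5] * 3, omega=[0, 1, -1])
        assert expressing_count(pop, triangle_graph, 0) == 2
        pop.omega[:] = 0
        assert expressing_count(pop, triangle_graph, 0) == 0

    def test_bounded_by_degree(self, worked_example):
        g, pop = worked_example
        pop.omega[:] = 1
        for i in range(g.n):
            assert expressing_count(pop, g, i) <= g.degree[i]


class TestGoal:
    def test_isolated_belief_anchor(self, worked_example):
        g, pop = worked_example
        pop.omega[:] = 0
        pop.sigma[0] = 1.0
        for parse in ("social", "full"):
            assert goal(pop, g, 0, 1, parse).payoff == pytest.approx(0.0)
            assert goal(pop, g, 0, 0, parse).payoff == pytest.approx(-1.0)
            assert goal(pop, g, 0, -1, parse).payoff == pytest.approx(-2.0)

    def test_worked_example_social_parse(self, worked_example):
        # m=1, social = A(0,1)*1 = 2 -> /(m+1) = 1; v = 0.5 + 1 = 1.5
        g, pop = worked_example
        ev = goal(pop, g, 0, 1, "social")
        assert ev.anchor == pytest.approx(1.5)
        assert ev.payoff == pytest.approx(-0.5)
        assert goal(pop, g, 0, 0, "social").payoff == pytest.approx(-1.5)
        assert goal(pop, g, 0, -1, "social").payoff == pytest.approx(-2.5)

    def test_worked_example_full_parse(self, worked_example):
        # v = (0.5 + 2)/(1+1) = 1.25
        g, pop = worked_example
        assert goal(pop, g, 0, 1, "full").anchor == pytest.approx(1.25)

    def test_payoff_never_positive(self, worked_example, rng):
        g, pop = worked_example
        for _ in range(20):
            pop.omega[:] = rng.integers(-1, 2, size=g.n)
            for c in (-1, 0, 1):
                assert goal(pop, g, 0, c).payoff <= 0

    def test_unknown_parse_rejected(self, worked_example):
        g, pop = worked_example
        with pytest.raises(ValueError):
            goal(pop, g, 0, 1, "weird")
        with pytest.raises(ValueError):
            goal(pop, g, 0, 2)


class TestBestResponse:
    def test_worked_example_expresses_majority(self, worked_example, rng):
        g, pop = worked_example
        assert best_response(pop, g, 0, "social", rng) == 1

    def test_hard_core_override(self, rng):
        fx = make_fixture("two_hubs")
        assert best_response(fx.population, fx.graph, 0, "full", rng) == -1

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_nearest_candidate_equals_argmax(self, v):
        """round-to-nearest-candidate is exactly argmax of G = -|v - w|."""
        payoffs = {w: -abs(v - w) for w in (-1, 0, 1)}
        best = max(payoffs.values())
        argmax = {w for w, p in payoffs.items() if p == best}
        assert _kernels.nearest_candidate(v, 0.25) in argmax
        assert _kernels.nearest_candidate(v, 0.75) in argmax

    def test_exact_tie_is_fair(self):
        # v = 0.5: candidates 0 and +1 equidistant
        picks = [_kernels.nearest_candidate(0.5, u) for u in np.random.default_rng(1).random(10_000)]
        frac_one = np.mean(np.array(picks) == 1)
        assert set(picks) == {0, 1}
        assert abs(frac_one - 0.5) < 4 * 0.5 / np.sqrt(10_000)

    def test_first_selection_strength_threshold(self, rng):
        # no expressing neighbors: sigma > 1/2 voices the belief, < 1/2 stays silent
        g = Graph.from_edges(3, [(0, 1), (0, 2), (1, 2)])
        pop = make_population(b=[1, 1, 1], sigma=[0.8, 0.2, 0.5], omega=[0, 0, 0])
        assert best_response(pop, g, 0, "full", rng) == 1
        assert best_response(pop, g, 1, "full", rng) == 0


class TestDynamics:
    def test_all_hard_core_locks_minus_one(self, rng):
        seq = sample_degree_sequence(100, 2.2, rng)
        g = build_graph(seq, rng)
        pop = assign_population(g, 2, rng)
        pop.is_hc[:] = True
        pop.b[:] = -1
        pop.sigma[:] = 1.0
        for _ in range(10):
            time_unit_endogenous(pop, g, rng)
        assert np.all(pop.omega[pop.has_expressed] == -1)

    def test_hc_never_silent_in_run(self, rng):
        seq = sample_degree_sequence(500, 2.2, rng)
        g = build_graph(seq, rng)
        pop = assign_population(g, 3, rng)
        traj = run_endogenous(g, pop, rng, horizon=40)
        final = traj.final_population
        assert np.all(final.omega[final.is_hc & final.has_expressed] == -1)

    def test_mean_belief_constant(self, rng):
        seq = sample_degree_sequence(300, 2.2, rng)
        g = build_graph(seq, rng)
        pop = assign_population(g, 2, rng)
        b0 = float(pop.b.mean())
        traj = run_endogenous(g, pop, rng, horizon=20, stationarity=(0, 0.0))
        assert traj.mean_belief == pytest.approx(b0)
        assert float(traj.final_population.b.mean()) == pytest.approx(b0)

    def test_observables_bounded(self, rng):
        seq = sample_degree_sequence(300, 2.2, rng)
        g = build_graph(seq, rng)
        pop = assign_population(g, 3, rng)
        traj = run_endogenous(g, pop, rng, horizon=25)
        for arr in (traj.mean_omega, traj.r):
            assert np.all(arr >= -1) and np.all(arr <= 1)
        for arr in (traj.frac_plus, traj.frac_minus, traj.frac_silent):
            assert np.all(arr >= 0) and np.all(arr <= 1)

    def test_seed_determinism_bit_identical(self):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(55)
            seq = sample_degree_sequence(300, 2.2, rng)
            g = build_graph(seq, rng)
            pop = assign_population(g, 2, rng)
            out.append(run_endogenous(g, pop, rng, horizon=20))
        a, b = out
        assert np.array_equal(a.mean_omega, b.mean_omega)
        assert np.array_equal(a.final_population.omega, b.final_population.omega)

    def test_parse_variants_differ_in_bulk(self, rng):
        # the two normalizations lead to macroscopically different silence
        fs = {}
        for parse in ("social", "full"):
            rng2 = np.random.default_rng(9)
            seq = sample_degree_sequence(2000, 2.2, rng2)
            g = build_graph(seq, rng2)
            pop = assign_population(g, 3, rng2)
            traj = run_endogenous(g, pop, rng2, horizon=50, parse=parse)
            fs[parse] = traj.final.frac_silent
        assert fs["full"] > fs["social"]

    def test_heavier_tail_preserves_belief_expression_ordering(self):
        # lambda = 1.5: <b> still exceeds the final expressed mean at any K_c
        rng = np.random.default_rng(21)
        for kc in (3, 10):
            seq = sample_degree_sequence(2000, 1.5, rng)
            g = build_graph(seq, rng)
            pop = assign_population(g, kc, rng)
            traj = run_endogenous(g, pop, rng, horizon=50)
            assert traj.final.mean_omega < traj.mean_belief
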