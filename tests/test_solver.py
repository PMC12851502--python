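"""Grid value iteration, thresholds, greedy policy and the expectimax oracle."""

import numpy as np
import pytest

import painpomdp as pp
from painpomdp.solver import (
    DegeneratePolicyError,
    QFunction,
    ValueFunction,
    belief_grid,
)


@pytest.fixture(scope="module")
def two_action_solution(two_action_spec):
    return pp.value_iteration(two_action_spec)


class TestInterpolation:
    def test_exact_at_grid_points_and_linear_between(self):
        grid = belief_grid()
        V = ValueFunction(grid=grid, values=grid**2)
        assert pp.interpolate_value(V, 0.37) == V.values[37]
        mid = pp.interpolate_value(V, 0.375)
        assert mid == pytest.approx((V.values[37] + V.values[38]) / 2)

    def test_constant_function_stays_constant(self):
        V = ValueFunction(grid=belief_grid(), values=np.full(101, 7.5))
        for b in (0.0, 0.123, 0.999):
            assert pp.interpolate_value(V, b) == 7.5


class TestTwoActionClosedForm:
    def test_value_is_upper_envelope_of_terminal_lines(self, two_action_solution):
        V, Q = two_action_solution
        envelope = np.maximum(100 - 500 * V.grid, 200 * V.grid - 100)
        assert np.max(np.abs(V.values - envelope)) < 1e-8

    def test_minimum_at_line_crossing(self, two_action_solution):
        V, _ = two_action_solution
        i = int(np.argmin(V.values))
        assert V.grid[i] == pytest.approx(2 / 7, abs=0.005)
        # within one grid step's rise of the crossing value -300/7
        assert V.values[i] == pytest.approx(-300 / 7, abs=2.5)

    def test_thresholds_adjacent_with_no_deferral_region(self, two_action_solution):
        _, Q = two_action_solution
        b_act, b_rest = pp.decision_thresholds(Q)
        assert (b_act, b_rest) == (pytest.approx(0.28), pytest.approx(0.29))


class TestSolverStructure:
    def test_terminal_q_equals_expected_utility_exactly(self, default_solution, default_spec):
        _, Q = default_solution
        for name in ("act", "rest"):
            rho = np.array([
                pp.expected_utility(b, name, default_spec.utilities) for b in Q.grid
            ])
            assert np.array_equal(Q.q[name], rho)

    def test_value_function_is_convex(self, default_solution, three_action_solution):
        for V, _ in (default_solution, three_action_solution):
            assert np.min(np.diff(V.values, 2)) >= -1e-6

    def test_value_dominates_terminal_lines_with_equality_at_ends(self, default_solution):
        V, _ = default_solution
        act_line = 100 - 500 * V.grid
        rest_line = 200 * V.grid - 100
        assert np.all(V.values >= act_line - 1e-9)
        assert np.all(V.values >= rest_line - 1e-9)
        assert V.values[0] == pytest.approx(100.0)
        assert V.values[-1] == pytest.approx(100.0)

    def test_converged_fixed_point(self, default_solution, default_spec):
        V, Q = default_solution
        assert V.converged and V.residual < 1e-6
        V2, _ = pp.bellman_backup(V, default_spec)
        assert V2.residual < 1e-6
        assert np.max(np.abs(Q.values() - V.values)) < 1e-8

    def test_nonconvergence_warns_not_raises(self, default_spec):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            V, _ = pp.value_iteration(default_spec, max_sweeps=3)
        assert not V.converged

    def test_deferral_region_contains_uncertain_beliefs(self, default_solution):
        _, Q = default_solution
        b_act, b_rest = pp.decision_thresholds(Q)
        assert b_act < 0.5 < b_rest
        assert pp.greedy_action(Q, 0.5).name == "query"


class TestMonotonicity:
    def test_higher_query_cost_lowers_query_value_pointwise(self):
        specs = {c: pp.make_injury_pomdp({"actions": "act,rest,query",
                                          "utilities.injured.query": c})
                 for c in (-4, -16)}
        solutions = {c: pp.value_iteration(s) for c, s in specs.items()}
        assert np.all(solutions[-16][1].q["query"] <= solutions[-4][1].q["query"] + 1e-9)
        assert np.all(solutions[-16][0].values <= solutions[-4][0].values + 1e-9)
        # dearer probing shrinks the deferral region (set inclusion)
        lo = pp.decision_thresholds(solutions[-4][1])
        hi = pp.decision_thresholds(solutions[-16][1])
        assert hi[0] >= lo[0] and hi[1] <= lo[1]

    def test_less_informative_channel_lowers_query_value_at_uncertainty(self):
        specs = {ic: pp.make_injury_pomdp({"actions": "act,rest,query",
                                           "observations.query": ic})
                 for ic in ("HI", "LI")}
        q_half = {ic: pp.value_iteration(s)[1].interpolate("query", 0.5)
                  for ic, s in specs.items()}
        assert q_half["HI"] > q_half["LI"]


class TestGreedyPolicy:
    def test_commits_at_certainty(self, default_solution):
        _, Q = default_solution
        assert pp.greedy_action(Q, 0.0).name == "act"
        assert pp.greedy_action(Q, 1.0).name == "rest"

    def test_interior_exact_tie_prefers_query(self):
        grid = belief_grid()
        q = {"act": np.full(101, 1.0), "rest": np.zeros(101),
             "query": np.full(101, 1.0)}
        Q = QFunction(grid=grid, q=q, actions=(pp.ACT, pp.REST, pp.QUERY))
        assert pp.greedy_action(Q, 0.5).name == "query"

    def test_policy_is_grid_based(self, default_solution):
        """Off-grid beliefs behave as their nearest grid point."""
        _, Q = default_solution
        assert pp.greedy_action(Q, 0.004).name == pp.greedy_action(Q, 0.0).name
        assert pp.greedy_action(Q, 0.507).name == pp.greedy_action(Q, 0.51).name

    def test_degenerate_policy_raises(self):
        spec = pp.make_injury_pomdp({
            "actions": "act,rest,query",
            "utilities.healthy.act": -1000, "utilities.injured.act": -1000,
            "utilities.healthy.rest": -1000, "utilities.injured.rest": -1000,
        })
        _, Q = pp.value_iteration(spec)
        with pytest.raises(DegeneratePolicyError):
            pp.decision_thresholds(Q)


class TestExpectimaxOracle:
    def test_horizon_one_commits_when_deferral_cannot_pay(self, tiny_spec):
        # a single query step cannot change the best commitment from b=0.5,
        # so the one-step tree value is the best terminal utility
        u = tiny_spec.utilities
        for b in (0.02, 0.98):
            best_terminal = max(
                pp.expected_utility(b, a, u) for a in tiny_spec.terminal_actions
            )
            assert pp.finite_horizon_expectimax(tiny_spec, b, 1) >= best_terminal

    def test_value_nondecreasing_in_horizon(self, tiny_spec):
        for b in (0.1, 0.5, 0.8):
            values = [pp.finite_horizon_expectimax(tiny_spec, b, h) for h in (1, 2, 4, 6)]
            assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(values, values[1:]))

    def test_agrees_with_grid_value_iteration(self, tiny_spec):
        V, _ = pp.value_iteration(tiny_spec)
        for b in V.grid[::10]:
            oracle = pp.finite_horizon_expectimax(tiny_spec, float(b), 8)
            assert abs(oracle - pp.interpolate_value(V, float(b))) < 0.5

    def test_node_budget_enforced(self, tiny_spec):
        with pytest.raises(pp.solver.NodeBudgetExceededError):
            pp.finite_horizon_expectimax(tiny_spec, 0.5, 8, node_budget=10)
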