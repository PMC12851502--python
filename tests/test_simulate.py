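"""Episode simulation: sampling, traces, batches and calibration."""

import numpy as np
import pytest

import painpomdp as pp
from painpomdp.simulate import episode_rngs


class TestSampleObservation:
    def test_empirical_mean_matches_channel(self, default_spec, rng):
        om = default_spec.obs_models["query"]
        draws = np.array([
            pp.sample_observation(1, "query", om, rng) for _ in range(10_000)
        ])
        model_mean = om.state_means()[1]
        model_sd = np.sqrt(om.pmf[1] @ (om.support - model_mean) ** 2)
        assert abs(draws.mean() - model_mean) < 3 * model_sd / 100.0

    def test_state_conditional_means_separated(self, default_spec):
        om = default_spec.obs_models["query"]
        rng0, rng1 = np.random.default_rng(7), np.random.default_rng(7)
        m0 = np.mean([pp.sample_observation(0, "query", om, rng0) for _ in range(8000)])
        m1 = np.mean([pp.sample_observation(1, "query", om, rng1) for _ in range(8000)])
        assert m1 - m0 == pytest.approx(15.0, abs=0.7)

    def test_deterministic_given_seed(self, default_spec):
        om = default_spec.obs_models["null"]
        a = [pp.sample_observation(0, "null", om, np.random.default_rng(3)) for _ in range(50)]
        b = [pp.sample_observation(0, "null", om, np.random.default_rng(3)) for _ in range(50)]
        assert a == b

    def test_terminal_action_rejected(self, default_spec, rng):
        with pytest.raises(ValueError, match="terminal"):
            pp.sample_observation(0, "act", default_spec.obs_models["query"], rng)


class TestSimulateEpisode:
    def test_certain_health_commits_to_act_immediately(self, three_action_spec,
                                                       three_action_solution, rng):
        _, Q = three_action_solution
        trace = pp.simulate_episode(three_action_spec, Q, true_state=0, b0=0.0, rng=rng)
        assert trace.length == 1
        assert trace.terminal_action.name == "act"
        assert trace.steps[0].feedback == 100.0

    def test_certain_injury_commits_to_rest_immediately(self, three_action_spec,
                                                        three_action_solution, rng):
        _, Q = three_action_solution
        trace = pp.simulate_episode(three_action_spec, Q, true_state=1, b0=1.0, rng=rng)
        assert trace.length == 1
        assert trace.terminal_action.name == "rest"
        assert trace.steps[0].feedback == 100.0

    def test_uncertain_start_probes_before_committing(self, three_action_spec,
                                                      three_action_solution, rng):
        _, Q = three_action_solution
        trace = pp.simulate_episode(three_action_spec, Q, true_state=1, b0=0.5, rng=rng)
        query_steps = [s for s in trace.steps if s.action.name == "query"]
        assert len(query_steps) >= 1
        assert all(s.feedback == -4.0 for s in query_steps)

    def test_trace_invariants_and_replay(self, three_action_spec,
                                         three_action_solution, rng):
        """Recorded beliefs replay exactly through the Bayes update."""
        _, Q = three_action_solution
        for state in (0, 1):
            trace = pp.simulate_episode(three_action_spec, Q, state, 0.5, rng)
            terminal_steps = [s for s in trace.steps if s.action.terminal]
            assert len(terminal_steps) <= 1
            if terminal_steps:
                assert trace.steps[-1].action.terminal
            assert trace.length <= three_action_spec.max_trials + 1
            b = trace.b0
            for step in trace.steps:
                assert step.belief == b
                if step.action.terminal:
                    assert step.observation is None
                else:
                    assert step.observation is not None
                    b = pp.belief_update(
                        b, step.action, step.observation,
                        three_action_spec.obs_models[step.action.name],
                    )
            assert trace.final_belief == b

    def test_truncation_at_trial_cap(self, rng):
        spec = pp.make_injury_pomdp({"actions": "act,rest,query", "max_trials": 2})
        _, Q = pp.value_iteration(spec)
        traces = [pp.simulate_episode(spec, Q, 0, 0.5, np.random.default_rng(i))
                  for i in range(50)]
        truncated = [t for t in traces if t.terminal_action is None]
        assert truncated, "two trials cannot resolve the state in every episode"
        assert all(t.length <= 2 for t in truncated)


class TestRunBatch:
    def test_bit_reproducible_given_seed(self, three_action_spec, three_action_solution):
        _, Q = three_action_solution
        a = pp.run_batch(three_action_spec, Q, 1, 0.5, 40, base_seed=9)
        b = pp.run_batch(three_action_spec, Q, 1, 0.5, 40, base_seed=9)
        assert a.terminal_action_counts == b.terminal_action_counts
        assert np.array_equal(a.mean_belief_trajectory, b.mean_belief_trajectory)
        assert np.array_equal(a.per_episode_returns, b.per_episode_returns)

    def test_counts_partition_episodes(self, three_action_spec, three_action_solution):
        _, Q = three_action_solution
        s = pp.run_batch(three_action_spec, Q, 1, 0.5, 60, base_seed=2)
        assert sum(s.terminal_action_counts.values()) == 60
        assert np.all((s.mean_belief_trajectory >= 0) & (s.mean_belief_trajectory <= 1))

    @pytest.mark.parametrize("state, expected_majority", [(1, "rest"), (0, "act")])
    def test_majority_commitment_matches_true_state(self, three_action_spec,
                                                    three_action_solution,
                                                    state, expected_majority):
        _, Q = three_action_solution
        s = pp.run_batch(three_action_spec, Q, state, 0.5, 300, base_seed=11)
        assert s.proportion(expected_majority) > 0.5

    def test_final_beliefs_are_calibrated(self, three_action_spec, three_action_solution):
        """Among episodes ending confident of injury, the state usually is injury."""
        _, Q = three_action_solution
        confident_injured = {0: 0, 1: 0}
        for state in (0, 1):
            batch = pp.run_batch(three_action_spec, Q, state, 0.5, 250, base_seed=21)
            confident_injured[state] = int(np.sum(batch.final_beliefs > 0.9))
        total = confident_injured[0] + confident_injured[1]
        assert total > 0
        assert confident_injured[1] / total > 0.9

    def test_mean_return_bounded_by_solved_value(self, three_action_spec,
                                                 three_action_solution):
        """Realised greedy returns cannot beat the optimal value at b0."""
        V, Q = three_action_solution
        b0, n = 0.5, 400
        rng = np.random.default_rng(5)
        states = rng.random(n) < b0  # prior-consistent true states
        returns = np.array([
            pp.simulate_episode(three_action_spec, Q, int(s), b0,
                                np.random.default_rng(1000 + i)).total_return
            for i, s in enumerate(states)
        ])
        se = returns.std(ddof=1) / np.sqrt(n)
        assert returns.mean() <= pp.interpolate_value(V, b0) + 3 * se

    def test_seed_streams_are_stable(self):
        streams = episode_rngs(123, 3)
        again = episode_rngs(123, 3)
        for a, b in zip(streams, again):
            assert a.integers(0, 1000, 5).tolist() == b.integers(0, 1000, 5).tolist()
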