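"""Greedy-policy episode simulation and batch aggregation.

An episode fixes the true hidden state, starts from belief ``b0``, and loops:
take the greedy action at the current belief; terminal actions collect their
feedback and end the episode, non-terminal actions collect theirs, draw an
observation from the true-state channel, and update the belief. Episodes
truncate after ``max_trials`` non-terminal steps. Batches aggregate episode
traces into mean belief trajectories (terminal beliefs carried forward),
terminal-action counts and pain summaries.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import pain
from .beliefs import belief_update
from .model import Action, ModelSpec, ObservationModel, as_action
from .solver import QFunction, greedy_action


class Step(NamedTuple):
    t: int
    belief: float
    action: Action
    observation: float | None
    feedback: float


@dataclasses.dataclass
class EpisodeTrace:
    """Time-indexed record of one simulated decision-making episode."""

    true_state: int
    b0: float
    steps: list[Step]
    terminal_action: Action | None  # None if truncated at the trial cap
    final_belief: float  # belief when the episode ended (after the last update)

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def total_return(self) -> float:
        return sum(s.feedback for s in self.steps)

    def n_action(self, action: "Action | str") -> int:
        name = as_action(action).name
        return sum(1 for s in self.steps if s.action.name == name)

    def to_frame(self, episode: int = 0, utilities=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "episode": episode,
                "t": [s.t for s in self.steps],
                "belief": [s.belief for s in self.steps],
                "action": [s.action.name for s in self.steps],
                "observation": [s.observation for s in self.steps],
                "feedback": [s.feedback for s in self.steps],
                "terminal_flag": [s.action.terminal for s in self.steps],
            }
        )
        if utilities is not None:
            frame["phasic_expected"] = [
                pain.phasic_pain(s.belief, s.action, utilities) for s in self.steps
            ]
            frame["tonic"] = [pain.tonic_pain(s.belief) for s in self.steps]
        return frame


def sample_observation(
    true_state: int,
    action: "Action | str",
    om: ObservationModel,
    rng: np.random.Generator,
):
    """Draw one observation from the true-state channel of ``action``."""
    a = as_action(action)
    if a.terminal:
        raise ValueError(f"terminal action {a.name!r} yields no observation")
    idx = rng.choice(om.n, p=om.pmf[true_state])
    return om.support[idx]


def simulate_episode(
    spec: ModelSpec,
    Q: QFunction,
    true_state: int,
    b0: float,
    rng: np.random.Generator,
) -> EpisodeTrace:
    """Run one episode under the greedy policy for ``Q``."""
    if true_state not in (0, 1):
        raise ValueError("true_state must be 0 or 1")
    b = float(b0)
    steps: list[Step] = []
    terminal: Action | None = None
    for t in range(spec.max_trials + 1):
        a = greedy_action(Q, b)
        feedback = spec.utilities.value(true_state, a)
        if a.terminal:
            steps.append(Step(t, b, a, None, feedback))
            terminal = a
            break
        if t == spec.max_trials:  # cap on non-terminal steps reached
            break
        om = spec.obs_models[a.name]
        o = sample_observation(true_state, a, om, rng)
        steps.append(Step(t, b, a, float(o), feedback))
        b = belief_update(b, a, o, om)
    return EpisodeTrace(true_state=true_state, b0=float(b0), steps=steps,
                        terminal_action=terminal, final_belief=b)


@dataclasses.dataclass
class BatchSummary:
    """Episode-averaged summaries of a batch of simulated episodes.

    Mean belief trajectories are indexed by trial 0..max_trials, carrying
    each episode's final belief forward after termination so the average is
    defined at every trial index. ``conditioned_trajectories`` restrict the
    average to episodes sharing a terminal action.
    """

    n_episodes: int
    true_state: int
    b0: float
    base_seed: int
    mean_belief_trajectory: np.ndarray
    conditioned_trajectories: dict[str, np.ndarray]
    terminal_action_counts: dict[str, int]
    mean_cumulative_phasic_pain: float
    per_episode_returns: np.ndarray
    final_beliefs: np.ndarray
    mean_length: float
    mean_final_belief: float
    mean_action_counts: dict[str, float]
    first_actions: dict[str, int]

    def proportion(self, outcome: str) -> float:
        return self.terminal_action_counts.get(outcome, 0) / self.n_episodes

    def trajectory_frame(self) -> pd.DataFrame:
        data = {"trial": np.arange(self.mean_belief_trajectory.size),
                "mean_belief": self.mean_belief_trajectory}
        for name, traj in self.conditioned_trajectories.items():
            data[f"mean_belief_{name}"] = traj
        return pd.DataFrame(data)


def episode_rngs(base_seed: int, n_episodes: int) -> list[np.random.Generator]:
    """Independent per-episode generators, deterministically derived.

    Uses ``SeedSequence(base_seed).spawn`` so episode streams are
    reproducible and statistically independent by contract.
    """
    children = np.random.SeedSequence(base_seed).spawn(n_episodes)
    return [np.random.default_rng(c) for c in children]


def _padded_beliefs(trace: EpisodeTrace, horizon: int) -> np.ndarray:
    beliefs = [s.belief for s in trace.steps if not s.action.terminal]
    beliefs.append(trace.final_belief)
    out = np.empty(horizon + 1)
    out[: len(beliefs)] = beliefs[: horizon + 1]
    out[len(beliefs):] = beliefs[-1]
    return out


def run_batch(
    spec: ModelSpec,
    Q: QFunction,
    true_state: int,
    b0: float,
    n_episodes: int,
    base_seed: int,
    keep_traces: bool = False,
) -> "BatchSummary | tuple[BatchSummary, list[EpisodeTrace]]":
    """Simulate ``n_episodes`` greedy episodes and aggregate them.

    Bit-reproducible given ``base_seed``. With ``keep_traces`` the raw
    episode traces are returned alongside the summary.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    horizon = spec.max_trials
    rngs = episode_rngs(base_seed, n_episodes)
    traj_sum = np.zeros(horizon + 1)
    cond_sums: dict[str, np.ndarray] = {
        "act": np.zeros(horizon + 1), "rest": np.zeros(horizon + 1)
    }
    counts = {"act": 0, "rest": 0, "truncated": 0}
    first_actions: dict[str, int] = {}
    action_count_sums: dict[str, float] = {a.name: 0.0 for a in spec.actions}
    returns = np.empty(n_episodes)
    finals = np.empty(n_episodes)
    cum_phasic = 0.0
    lengths = 0.0
    traces: list[EpisodeTrace] = []
    for i in range(n_episodes):
        trace = simulate_episode(spec, Q, true_state, b0, rngs[i])
        padded = _padded_beliefs(trace, horizon)
        traj_sum += padded
        outcome = trace.terminal_action.name if trace.terminal_action else "truncated"
        counts[outcome] = counts.get(outcome, 0) + 1
        if outcome in cond_sums:
            cond_sums[outcome] += padded
        if trace.steps:
            first = trace.steps[0].action.name
            first_actions[first] = first_actions.get(first, 0) + 1
        for name in action_count_sums:
            action_count_sums[name] += trace.n_action(name)
        returns[i] = trace.total_return
        finals[i] = trace.final_belief
        cum_phasic += pain.cumulative_phasic_pain(trace, spec.utilities)
        lengths += trace.length
        if keep_traces:
            traces.append(trace)
    cond = {
        name: (s / counts[name] if counts.get(name, 0) else np.full(horizon + 1, np.nan))
        for name, s in cond_sums.items()
    }
    summary = BatchSummary(
        n_episodes=n_episodes,
        true_state=true_state,
        b0=float(b0),
        base_seed=base_seed,
        mean_belief_trajectory=traj_sum / n_episodes,
        conditioned_trajectories=cond,
        terminal_action_counts=counts,
        mean_cumulative_phasic_pain=cum_phasic / n_episodes,
        per_episode_returns=returns,
        final_beliefs=finals,
        mean_length=lengths / n_episodes,
        mean_final_belief=float(finals.mean()),
        mean_action_counts={k: v / n_episodes for k, v in action_count_sums.items()},
        first_actions=first_actions,
    )
    return (summary, traces) if keep_traces else summary
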