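"""Bayesian belief-state machinery.

With a static hidden state the belief is a single scalar ``b = P(injured)``,
a sufficient statistic for the whole action-observation history. The posterior
after observing ``o`` under a non-terminal action reduces to

    b' = P(o|s=1) b / (P(o|s=1) b + P(o|s=0) (1 - b))

and the one-step expected utility on beliefs is
``rho(b, a) = b r(1,a) + (1-b) r(0,a)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model import Action, ObservationModel, UtilityTable, as_action

#: likelihoods below this are treated as exactly zero (discretised Gaussian
#: tails underflow near the support edges)
LIKELIHOOD_FLOOR = 1e-300


class ZeroProbabilityObservationError(ValueError):
    """Bayes update conditioned on an observation of probability zero."""


def _require_nonterminal(action: "Action | str") -> Action:
    a = as_action(action)
    if a.terminal:
        raise ValueError(f"action {a.name!r} is terminal and yields no observation")
    return a


def expected_utility(b: float, action: "Action | str", utilities: UtilityTable) -> float:
    """One-step expected feedback rho(b, a) = b r(1,a) + (1-b) r(0,a)."""
    a = as_action(action)
    return b * utilities.value(1, a) + (1.0 - b) * utilities.value(0, a)


def marginal_observation_prob(
    b: float, action: "Action | str", om: ObservationModel
) -> np.ndarray:
    """P(o | b, a) over the full support: the belief-weighted pmf mixture."""
    _require_nonterminal(action)
    return b * om.pmf[1] + (1.0 - b) * om.pmf[0]


def belief_update(
    b: float, action: "Action | str", o, om: ObservationModel
) -> float:
    """Posterior belief after observing ``o`` (static-state Bayes rule)."""
    a = _require_nonterminal(action)
    l0, l1 = om.likelihoods(o)
    if l0 < LIKELIHOOD_FLOOR:
        l0 = 0.0
    if l1 < LIKELIHOOD_FLOOR:
        l1 = 0.0
    denom = l1 * b + l0 * (1.0 - b)
    if denom == 0.0:
        raise ZeroProbabilityObservationError(
            f"observation {o!r} has probability 0 under belief {b} and action {a.name!r}"
        )
    return l1 * b / denom


@dataclasses.dataclass(frozen=True)
class BeliefTransitionKernel:
    """All one-step belief transitions from ``source`` under one action.

    ``probs`` are the marginal observation probabilities and ``successors``
    the corresponding posterior beliefs. Because the hidden state is static,
    Bayesian beliefs are a martingale: ``probs @ successors == source``.
    """

    source: float
    action: str
    observations: np.ndarray
    probs: np.ndarray
    successors: np.ndarray

    def mean_abs_update(self) -> float:
        """E|b' - b| — the expected belief-update magnitude."""
        return float(self.probs @ np.abs(self.successors - self.source))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_belief": self.source,
                "action": self.action,
                "observation": self.observations,
                "probability": self.probs,
                "successor_belief": self.successors,
            }
        )


def belief_transition_kernel(
    b: float, action: "Action | str", om: ObservationModel
) -> BeliefTransitionKernel:
    """Enumerate every observation with its probability and posterior."""
    a = _require_nonterminal(action)
    probs = marginal_observation_prob(b, a, om)
    successors = np.array(
        [
            belief_update(b, a, o, om) if p > 0.0 else b
            for o, p in zip(om.support, probs)
        ]
    )
    return BeliefTransitionKernel(
        source=b,
        action=a.name,
        observations=om.support.copy(),
        probs=probs,
        successors=successors,
    )
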