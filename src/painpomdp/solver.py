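"""Belief-grid value iteration for the injury POMDP.

The POMDP is solved as a belief MDP on a uniform grid over ``[0, 1]``
(default step 0.01). Each Bellman backup evaluates, at every grid belief,

    q(b, a_terminal)    = rho(b, a)
    q(b, a_nonterminal) = rho(b, a) + gamma * sum_o P(o|b,a) V(b'(b,a,o))
    V(b)                = max_a q(b, a)

with successor beliefs kept exact and the current value function evaluated
by linear interpolation, consistent with the piecewise-linear-and-convex
(PWLC) structure of optimal POMDP value functions. A finite-horizon
expectimax over the full observation tree serves as an independent oracle
on small fixtures.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from . import beliefs
from .model import Action, ModelSpec, as_action

GRID_STEP = 0.01

#: exact ties at interior beliefs go to the deferring actions (the decision
#: thresholds are the most uncertain beliefs where a terminal action first
#: wins); at the degenerate beliefs 0 and 1 observations carry no information,
#: so deferral cannot beat commitment and terminal actions win ties instead.
TIE_PRIORITY = ("query", "null", "rest", "act")
ENDPOINT_TIE_PRIORITY = ("act", "rest", "query", "null")


class DegeneratePolicyError(RuntimeError):
    """No belief prefers a terminal action at one end of the grid."""


class NodeBudgetExceededError(RuntimeError):
    """Expectimax tree grew past the configured node budget."""


def belief_grid(step: float = GRID_STEP) -> np.ndarray:
    """Uniform belief grid including both endpoints 0 and 1."""
    n = round(1.0 / step)
    return np.linspace(0.0, 1.0, n + 1)


@dataclasses.dataclass
class ValueFunction:
    grid: np.ndarray
    values: np.ndarray
    converged: bool = True
    sweeps: int = 0
    residual: float = 0.0


@dataclasses.dataclass
class QFunction:
    """Per-action values on the belief grid.

    ``q`` maps action name -> values per grid point; terminal actions hold
    exactly their expected-utility line (termination yields no continuation).
    """

    grid: np.ndarray
    q: Mapping[str, np.ndarray]
    actions: tuple[Action, ...]

    def interpolate(self, action: "Action | str", b: float) -> float:
        return float(np.interp(b, self.grid, self.q[as_action(action).name]))

    def values(self) -> np.ndarray:
        """max_a q(b, a) per grid point."""
        return np.max(np.stack([self.q[a.name] for a in self.actions]), axis=0)


def interpolate_value(V: ValueFunction, b: float) -> float:
    """PWLC-consistent off-grid evaluation; exact at grid points."""
    return float(np.interp(b, V.grid, V.values))


class _BackupCache:
    """Per-model precomputation shared across Bellman sweeps.

    For each non-terminal action, stores the marginal observation matrix
    ``P[i, j] = P(o_j | b_i, a)`` and the successor-belief matrix
    ``B[i, j] = b'(b_i, a, o_j)`` over the grid.
    """

    def __init__(self, spec: ModelSpec, grid: np.ndarray):
        self.spec = spec
        self.grid = grid
        self.rho = {
            a.name: grid * spec.utilities.value(1, a)
            + (1.0 - grid) * spec.utilities.value(0, a)
            for a in spec.actions
        }
        self.marginals: dict[str, np.ndarray] = {}
        self.successors: dict[str, np.ndarray] = {}
        b = grid[:, None]
        for a in spec.nonterminal_actions:
            om = spec.obs_models[a.name]
            l0 = np.where(om.pmf[0] < beliefs.LIKELIHOOD_FLOOR, 0.0, om.pmf[0])
            l1 = np.where(om.pmf[1] < beliefs.LIKELIHOOD_FLOOR, 0.0, om.pmf[1])
            marg = b * l1 + (1.0 - b) * l0
            with np.errstate(invalid="ignore", divide="ignore"):
                succ = np.where(marg > 0.0, b * l1 / marg, b)
            self.marginals[a.name] = marg
            self.successors[a.name] = succ


def bellman_backup(
    V: ValueFunction, spec: ModelSpec, _cache: _BackupCache | None = None
) -> tuple[ValueFunction, QFunction]:
    """One Bellman optimality backup over the whole grid."""
    cache = _cache or _BackupCache(spec, V.grid)
    q: dict[str, np.ndarray] = {}
    for a in spec.actions:
        if a.terminal:
            q[a.name] = cache.rho[a.name].copy()
        else:
            succ_values = np.interp(cache.successors[a.name], V.grid, V.values)
            continuation = (cache.marginals[a.name] * succ_values).sum(axis=1)
            q[a.name] = cache.rho[a.name] + spec.gamma * continuation
    qfun = QFunction(grid=V.grid, q=q, actions=spec.actions)
    new_values = qfun.values()
    new_V = ValueFunction(
        grid=V.grid,
        values=new_values,
        converged=V.converged,
        sweeps=V.sweeps + 1,
        residual=float(np.max(np.abs(new_values - V.values))),
    )
    return new_V, qfun


def value_iteration(
    spec: ModelSpec,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    grid_step: float = GRID_STEP,
) -> tuple[ValueFunction, QFunction]:
    """Iterate Bellman backups from V0 = 0 to the fixed point.

    Converges at ``gamma = 1`` because the terminating actions bound the
    value while the strictly negative per-step deferral costs make infinite
    deferral suboptimal. Non-convergence within ``max_sweeps`` returns the
    last iterate with ``converged=False`` and a warning.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    grid = belief_grid(grid_step)
    cache = _BackupCache(spec, grid)
    V = ValueFunction(grid=grid, values=np.zeros_like(grid), sweeps=0)
    qfun: QFunction
    for _ in range(max_sweeps):
        V, qfun = bellman_backup(V, spec, cache)
        if V.residual < tol:
            V.converged = True
            return V, qfun
    V.converged = False
    warnings.warn(
        f"value iteration did not converge in {max_sweeps} sweeps "
        f"(residual {V.residual:.3g} >= tol {tol:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return V, qfun


def greedy_action(Q: QFunction, b: float) -> Action:
    """Grid policy: argmax_a q at the grid belief nearest to ``b``.

    The simulated policy is the grid-based one the solver actually
    optimises: off-grid beliefs act like their nearest grid point, so the
    commitment regions are unions of grid cells (in particular, beliefs
    that have resolved to within half a grid step of an endpoint commit).
    Exact ties go to deferring actions (query > null > rest > act) at
    interior grid points and to terminal actions at the degenerate beliefs
    0 and 1, where observations are uninformative and deferral cannot pay.
    """
    idx = int(np.abs(Q.grid - b).argmin())
    values = {a.name: float(Q.q[a.name][idx]) for a in Q.actions}
    best = max(values.values())
    endpoint = idx == 0 or idx == Q.grid.size - 1
    priority = ENDPOINT_TIE_PRIORITY if endpoint else TIE_PRIORITY
    for name in priority:
        if name in values and values[name] == best:
            return as_action(name)
    raise AssertionError("unreachable: no action achieved its own maximum")


def greedy_actions_on_grid(Q: QFunction) -> list[Action]:
    return [greedy_action(Q, float(b)) for b in Q.grid]


def decision_thresholds(Q: QFunction) -> tuple[float, float]:
    """Decision thresholds (b_act, b_rest) on the grid.

    ``b_act`` is the largest grid belief up to which ``act`` stays greedy
    scanning from 0; ``b_rest`` the smallest down from 1 with ``rest``
    greedy. Beliefs strictly between them defer.
    """
    greedy = greedy_actions_on_grid(Q)
    if greedy[0].name != "act" or greedy[-1].name != "rest":
        raise DegeneratePolicyError(
            "no terminal action is greedy at a grid endpoint: "
            f"greedy(0)={greedy[0].name}, greedy(1)={greedy[-1].name}"
        )
    i = 0
    while i + 1 < len(greedy) and greedy[i + 1].name == "act":
        i += 1
    j = len(greedy) - 1
    while j - 1 >= 0 and greedy[j - 1].name == "rest":
        j -= 1
    b_act, b_rest = float(Q.grid[i]), float(Q.grid[j])
    if b_act > b_rest:
        raise DegeneratePolicyError(
            f"threshold ordering violated: b_act={b_act} > b_rest={b_rest}"
        )
    return b_act, b_rest


def finite_horizon_expectimax(
    spec: ModelSpec,
    b: float,
    horizon: int,
    node_budget: int = 2_000_000,
) -> float:
    """Exact expectimax over the full observation tree (solver oracle).

    No grid, no interpolation: terminal actions close the tree with their
    expected utility; non-terminal actions recurse over every observation;
    at horizon exhaustion the value is the best terminal commitment.
    Beliefs reached by permuted observation sequences coincide, so results
    are memoised on (depth, belief) with the belief rounded to 12 decimals.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    u = spec.utilities
    nonterminal = [
        (a, spec.obs_models[a.name]) for a in spec.nonterminal_actions
    ]
    memo: dict[tuple[int, float], float] = {}
    nodes = 0

    def rec(belief: float, depth: int) -> float:
        nonlocal nodes
        nodes += 1
        if nodes > node_budget:
            raise NodeBudgetExceededError(
                f"expectimax exceeded node budget of {node_budget}"
            )
        best = max(
            beliefs.expected_utility(belief, a, u) for a in spec.terminal_actions
        )
        if depth >= horizon:
            return best
        key = (depth, round(belief, 12))
        cached = memo.get(key)
        if cached is not None:
            return cached
        for a, om in nonterminal:
            marg = beliefs.marginal_observation_prob(belief, a, om)
            continuation = 0.0
            for o, p in zip(om.support, marg):
                if p <= 0.0:
                    continue
                continuation += p * rec(beliefs.belief_update(belief, a, o, om), depth + 1)
            value = beliefs.expected_utility(belief, a, u) + spec.gamma * continuation
            if value > best:
                best = value
        memo[key] = best
        return best

    return rec(b, 0)


def q_table(spec: ModelSpec, V: ValueFunction, Q: QFunction) -> pd.DataFrame:
    """Solved values per grid belief, the data behind Q-curve plots."""
    data: dict[str, object] = {"belief": Q.grid, "V": V.values}
    for name in ("act", "rest", "query", "null"):
        if name in Q.q:
            data[f"q_{name}"] = Q.q[name]
    data["greedy_action"] = [a.name for a in greedy_actions_on_grid(Q)]
    return pd.DataFrame(data)
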