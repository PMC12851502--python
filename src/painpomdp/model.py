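"""Injury-POMDP model definition.

The model is a two-state partially observable decision problem: the hidden
state is ``0`` (healthy) or ``1`` (injured) and stays fixed within an episode.
The agent chooses among a small action set — committing to demanding activity
(``act``), resting and recuperating (``rest``), probing the injury (``query``),
or doing nothing (``null``). ``act`` and ``rest`` terminate the episode;
``query`` and ``null`` defer commitment and return a noisy observation of the
hidden state through a discretised Gaussian channel.

Utilities are internal feedback signals ``r(s, a)`` in dimensionless utility
units; the subset flagged as pain-system feedback (``zeta``) drives the phasic
pain readout.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.stats import norm

STATE_HEALTHY = 0
STATE_INJURED = 1
STATES = (STATE_HEALTHY, STATE_INJURED)

#: info-gain classes: name -> (separation of state-conditional means, sd)
INFO_CLASSES = {"HI": (15.0, 15.0), "LI": (5.0, 30.0)}


class ConfigurationError(ValueError):
    """Invalid or inconsistent model configuration."""


@dataclasses.dataclass(frozen=True)
class Action:
    """An action label with its termination flag."""

    name: str
    terminal: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


ACT = Action("act", terminal=True)
REST = Action("rest", terminal=True)
QUERY = Action("query", terminal=False)
NULL = Action("null", terminal=False)

ACTIONS_BY_NAME = {a.name: a for a in (ACT, REST, QUERY, NULL)}


def as_action(action: "Action | str") -> Action:
    """Coerce an action name to its :class:`Action`."""
    if isinstance(action, Action):
        return action
    try:
        return ACTIONS_BY_NAME[action]
    except KeyError:
        raise ConfigurationError(f"unknown action {action!r}") from None


@dataclasses.dataclass(frozen=True)
class UtilityTable:
    """Feedback signals ``r(s, a)`` and the pain-system subset ``zeta``.

    ``zeta`` entries must be non-positive and equal the corresponding ``r``
    entry; in the default model only the ``query`` action carries
    pain-system feedback.
    """

    r: Mapping[tuple[int, str], float]
    zeta: Mapping[tuple[int, str], float]

    def value(self, state: int, action: "Action | str") -> float:
        name = as_action(action).name
        try:
            return self.r[(state, name)]
        except KeyError:
            raise ConfigurationError(
                f"no utility defined for state={state}, action={name!r}"
            ) from None

    def pain_feedback(self, state: int, action: "Action | str") -> float:
        """zeta(s, a); 0 for actions with no pain-system entry."""
        return self.zeta.get((state, as_action(action).name), 0.0)

    def validate(self, actions: tuple[Action, ...]) -> None:
        for a in actions:
            for s in STATES:
                if (s, a.name) not in self.r:
                    raise ConfigurationError(
                        f"missing utility for state={s}, action={a.name!r}"
                    )
        null = ACTIONS_BY_NAME["null"]
        if null in actions and self.r[(0, "null")] != self.r[(1, "null")]:
            raise ConfigurationError("null-action utility must be state-independent")
        for key, z in self.zeta.items():
            if z > 0:
                raise ConfigurationError(f"zeta{key} = {z} must be <= 0")
            if key not in self.r or self.r[key] != z:
                raise ConfigurationError(f"zeta{key} must equal r{key}")


@dataclasses.dataclass(frozen=True)
class ObservationModel:
    """State-conditional pmfs over a finite ordered observation support.

    ``pmf`` has shape ``(2, len(support))``, row ``s`` giving ``P(o | s)``.
    """

    support: np.ndarray
    pmf: np.ndarray
    info_class: str
    mean_sep: float
    sd: float

    def __post_init__(self) -> None:
        if self.pmf.shape != (2, self.support.size):
            raise ConfigurationError("pmf must have shape (2, len(support))")
        if np.any(self.pmf < 0):
            raise ConfigurationError("observation pmf has negative entries")
        sums = self.pmf.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ConfigurationError(f"observation pmfs not normalised: sums={sums}")

    @property
    def n(self) -> int:
        return self.support.size

    def index(self, o) -> int:
        """Position of observation value ``o`` in the support."""
        idx = int(np.searchsorted(self.support, o))
        if idx >= self.n or self.support[idx] != o:
            raise ValueError(f"observation {o!r} not in support")
        return idx

    def likelihoods(self, o) -> tuple[float, float]:
        """(P(o|s=0), P(o|s=1))."""
        i = self.index(o)
        return float(self.pmf[0, i]), float(self.pmf[1, i])

    def state_means(self) -> tuple[float, float]:
        return tuple(float(p @ self.support) for p in self.pmf)  # type: ignore[return-value]


def build_observation_model(
    info_class: str,
    center: float = 50.0,
    step: float = 1.0,
    support_range: tuple[float, float] = (1.0, 100.0),
) -> ObservationModel:
    """Discretised-Gaussian observation channel for one info-gain class.

    The two state-conditional distributions are Gaussians separated by the
    class mean separation (healthy takes the lower mean, injured the higher),
    symmetric about ``center``, with the class sd, discretised onto the
    integer-spaced support by integrating the density over each unit bin
    ``[o - step/2, o + step/2]`` and renormalising.
    """
    try:
        mean_sep, sd = INFO_CLASSES[info_class]
    except KeyError:
        raise ConfigurationError(
            f"unknown info_class {info_class!r}; expected one of {sorted(INFO_CLASSES)}"
        ) from None
    return _discretised_gaussian_channel(
        info_class, mean_sep, sd, center, step, support_range
    )


def _discretised_gaussian_channel(
    info_class: str,
    mean_sep: float,
    sd: float,
    center: float,
    step: float,
    support_range: tuple[float, float],
) -> ObservationModel:
    lo, hi = support_range
    support = np.arange(lo, hi + step / 2, step)
    if support.size == 0:
        raise ConfigurationError("observation support is empty")
    means = (center - mean_sep / 2.0, center + mean_sep / 2.0)
    if not (lo <= means[0] and means[1] <= hi):
        raise ConfigurationError(
            f"state means {means} fall outside support [{lo}, {hi}]"
        )
    pmf = np.empty((2, support.size))
    for s, mu in enumerate(means):
        mass = norm.cdf(support + step / 2, mu, sd) - norm.cdf(
            support - step / 2, mu, sd
        )
        pmf[s] = mass / mass.sum()
    return ObservationModel(
        support=support, pmf=pmf, info_class=info_class, mean_sep=mean_sep, sd=sd
    )


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Complete injury-POMDP definition.

    State transitions are the identity within an episode (no transition
    matrix is stored); ``max_trials`` caps the number of non-terminal steps.
    """

    actions: tuple[Action, ...]
    utilities: UtilityTable
    obs_models: Mapping[str, ObservationModel]
    gamma: float = 1.0
    max_trials: int = 100

    def __post_init__(self) -> None:
        names = [a.name for a in self.actions]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate actions in {names}")
        for required in ("act", "rest"):
            if required not in names:
                raise ConfigurationError(f"action set must contain {required!r}")
        for extra in set(names) - set(ACTIONS_BY_NAME):
            raise ConfigurationError(f"unknown action {extra!r}")
        for a in self.actions:
            if a.terminal and a.name in self.obs_models:
                raise ConfigurationError(
                    f"terminal action {a.name!r} must not have an observation model"
                )
            if not a.terminal and a.name not in self.obs_models:
                raise ConfigurationError(
                    f"non-terminal action {a.name!r} needs an observation model"
                )
        if not (0.0 < self.gamma <= 1.0):
            raise ConfigurationError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.max_trials < 1:
            raise ConfigurationError("max_trials must be >= 1")
        self.utilities.validate(self.actions)

    @property
    def nonterminal_actions(self) -> tuple[Action, ...]:
        return tuple(a for a in self.actions if not a.terminal)

    @property
    def terminal_actions(self) -> tuple[Action, ...]:
        return tuple(a for a in self.actions if a.terminal)


# --- construction from flat dotted-key configs -------------------------------

_STATE_KEYS = {"healthy": STATE_HEALTHY, "injured": STATE_INJURED}

DEFAULT_CONFIG: dict[str, object] = {
    "actions": "act,rest,query,null",
    "utilities.healthy.act": 100.0,
    "utilities.healthy.rest": -100.0,
    "utilities.healthy.query": 0.0,
    "utilities.healthy.null": -0.5,
    "utilities.injured.act": -400.0,
    "utilities.injured.rest": 100.0,
    "utilities.injured.query": -4.0,
    "utilities.injured.null": -0.5,
    "observations.query": "HI",
    "observations.null": "LI",
    "observations.center": 50.0,
    "gamma": 1.0,
    "max_trials": 100,
}

#: key -> coercion applied to raw (possibly string) config values
CONFIG_SCHEMA: dict[str, type] = {
    k: (str if isinstance(v, str) else int if isinstance(v, int) else float)
    for k, v in DEFAULT_CONFIG.items()
}


def resolve_config(config: Mapping[str, object] | None = None) -> dict[str, object]:
    """Merge ``config`` over the defaults, rejecting unknown keys."""
    resolved = dict(DEFAULT_CONFIG)
    for key, raw in (config or {}).items():
        if key not in CONFIG_SCHEMA:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        caster = CONFIG_SCHEMA[key]
        try:
            resolved[key] = caster(raw)
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"configuration key {key!r}: cannot interpret {raw!r} as {caster.__name__}"
            ) from None
    return resolved


def make_injury_pomdp(config: Mapping[str, object] | None = None) -> ModelSpec:
    """Build a validated :class:`ModelSpec`; omitted keys take the defaults.

    The default model is the four-action injury POMDP:
    ``r(1,act)=-400, r(1,rest)=+100, r(1,query)=-4, r(0,act)=+100,
    r(0,rest)=-100, r(0,query)=0, r(null)=-0.5`` in both states; ``query``
    observes through the high-information (HI) channel and ``null`` through
    the low-information (LI) channel; ``gamma=1``; ``max_trials=100``.
    """
    cfg = resolve_config(config)
    names = [n.strip() for n in str(cfg["actions"]).split(",") if n.strip()]
    actions = tuple(as_action(n) for n in names)

    r: dict[tuple[int, str], float] = {}
    for state_word, s in _STATE_KEYS.items():
        for a in actions:
            r[(s, a.name)] = float(cfg[f"utilities.{state_word}.{a.name}"])
    # pain-system feedback: only injury probing carries it
    zeta = {(s, "query"): r[(s, "query")] for s in STATES if (s, "query") in r}
    utilities = UtilityTable(r=r, zeta=zeta)

    center = float(cfg["observations.center"])
    obs_models = {
        a.name: build_observation_model(str(cfg[f"observations.{a.name}"]), center)
        for a in actions
        if not a.terminal
    }
    return ModelSpec(
        actions=actions,
        utilities=utilities,
        obs_models=obs_models,
        gamma=float(cfg["gamma"]),
        max_trials=int(cfg["max_trials"]),
    )
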