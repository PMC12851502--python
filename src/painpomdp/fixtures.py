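"""Small models for oracle-scale validation.

``two_action`` strips the model to the terminal commitments only, whose
optimal value is the closed-form upper envelope of the two expected-utility
lines. ``tiny_obs`` keeps the full decision structure but shrinks the
observation support to 5 points so the finite-horizon expectimax oracle can
evaluate the exact tree. ``default`` is the full model.
"""

from __future__ import annotations

from .model import (
    ACT,
    QUERY,
    REST,
    ModelSpec,
    UtilityTable,
    _discretised_gaussian_channel,
    make_injury_pomdp,
)

FIXTURE_NAMES = ("two_action", "tiny_obs", "default")


def make_test_fixture(name: str) -> ModelSpec:
    """Build a named fixture model; see module docstring."""
    if name == "default":
        return make_injury_pomdp()
    if name == "two_action":
        r = {(1, "act"): -400.0, (1, "rest"): 100.0,
             (0, "act"): 100.0, (0, "rest"): -100.0}
        return ModelSpec(
            actions=(ACT, REST),
            utilities=UtilityTable(r=r, zeta={}),
            obs_models={},
        )
    if name == "tiny_obs":
        # informative 5-point channel: horizon-8 expectimax nearly resolves
        # the state, so the exact tree approximates the infinite horizon
        channel = _discretised_gaussian_channel(
            "HI", mean_sep=2.0, sd=0.8, center=3.0, step=1.0,
            support_range=(1.0, 5.0),
        )
        r = {(1, "act"): -400.0, (1, "rest"): 100.0, (1, "query"): -4.0,
             (0, "act"): 100.0, (0, "rest"): -100.0, (0, "query"): 0.0}
        zeta = {(0, "query"): 0.0, (1, "query"): -4.0}
        return ModelSpec(
            actions=(ACT, REST, QUERY),
            utilities=UtilityTable(r=r, zeta=zeta),
            obs_models={"query": channel},
        )
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
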