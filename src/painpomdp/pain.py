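"""Model correlates of pain.

Phasic pain is the belief-weighted expected pain-system feedback of an
action, ``sum_s b(s) zeta(s, a)`` — transient and event-locked, incurred at
each injury-probing step. Tonic pain is the belief assigned to the injured
state itself, ``b(s=1)``. Both proportionality constants are taken as 1, so
phasic pain is read on the utility scale and tonic pain on the belief scale.
"""

from __future__ import annotations

from .model import Action, UtilityTable, as_action


def phasic_pain(b: float, action: "Action | str", utilities: UtilityTable) -> float:
    """Expected pain-system feedback at belief ``b``: sum_s b(s) zeta(s, a).

    Only zeta-flagged entries contribute; actions without pain-system
    feedback return 0. Always <= 0.
    """
    a = as_action(action)
    return b * utilities.pain_feedback(1, a) + (1.0 - b) * utilities.pain_feedback(0, a)


def tonic_pain(b: float) -> float:
    """Ongoing pain drive: the belief in the injured state."""
    return b


def cumulative_phasic_pain(trace, utilities: UtilityTable) -> float:
    """Summed expected phasic pain over every step of an episode trace.

    Uses the belief held *before* each action (the expectation the agent
    acts under), not the realised feedback.
    """
    return sum(
        phasic_pain(step.belief, step.action, utilities) for step in trace.steps
    )
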