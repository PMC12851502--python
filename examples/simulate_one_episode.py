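"""Simulate one decision-making episode and print its trace with pain readouts.

The true state is injured and the agent starts maximally uncertain
(b0 = 0.5). Each row shows the belief before acting, the greedy action, the
observation drawn from the true-state channel, the realised feedback, and
the model pain correlates: phasic pain (belief-weighted probing cost) and
tonic pain (the injury belief itself).
"""

import numpy as np

import painpomdp as pp

spec = pp.make_injury_pomdp()
V, Q = pp.value_iteration(spec)
rng = np.random.default_rng(7)
trace = pp.simulate_episode(spec, Q, true_state=1, b0=0.5, rng=rng)

print("  t  belief  action  obs   feedback  phasic  tonic")
for s in trace.steps:
    obs = f"{s.observation:5.0f}" if s.observation is not None else "    -"
    phasic = pp.phasic_pain(s.belief, s.action, spec.utilities)
    print(f"{s.t:3d}  {s.belief:6.3f}  {s.action.name:6s} {obs} "
          f"{s.feedback:9.1f}  {phasic:6.2f}  {pp.tonic_pain(s.belief):5.3f}")

print()
print(f"terminal action: {trace.terminal_action.name}; "
      f"return {trace.total_return:+.1f}; "
      f"cumulative phasic pain "
      f"{pp.cumulative_phasic_pain(trace, spec.utilities):.2f}")
print("Each probe hurts in proportion to the current injury belief, but it")
print("buys the evidence needed to commit to the correct terminal action.")
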