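"""Solve the default injury POMDP and read off the decision thresholds.

Builds the four-action model (act / rest / query / null), runs belief-grid
value iteration, and prints the per-action values at a few beliefs together
with the commitment thresholds.
"""

import painpomdp as pp

spec = pp.make_injury_pomdp()
V, Q = pp.value_iteration(spec)
b_act, b_rest = pp.decision_thresholds(Q)

print(f"solver: converged={V.converged} after {V.sweeps} sweeps "
      f"(residual {V.residual:.2e})")
print(f"thresholds: commit to act at b <= {b_act:.2f}, "
      f"to rest at b >= {b_rest:.2f}")
print()
print("belief   q(act)   q(rest)  q(query)  q(null)   greedy")
for b in (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.94, 1.0):
    row = [Q.interpolate(a, b) for a in ("act", "rest", "query", "null")]
    print(f"  {b:4.2f} " + " ".join(f"{v:8.2f}" for v in row)
          + f"   {pp.greedy_action(Q, b).name}")
print()
print("Between the thresholds the agent defers commitment and probes the")
print("injury (query): the value of information outweighs the probing cost.")
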