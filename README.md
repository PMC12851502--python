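# painpomdp

A belief-state decision model of injury, investigation and pain.

`painpomdp` implements a small partially observable Markov decision process
(POMDP) in which an agent is uncertain whether it is injured (hidden state
`s ∈ {0, 1}`, healthy/injured, static within an episode) and must choose
between committing to demanding activity (`act`), resting and recuperating
(`rest`), or deferring commitment to gather noisy interoceptive evidence —
either by actively probing the injury (`query`, informative but aversive
when injured) or by doing nothing (`null`, cheap but uninformative). The
package is for computational-psychiatry and decision-neuroscience modellers
who want a reproducible sandbox for the idea that tonic pain tracks the
*belief* in injury and phasic pain the expected cost of probing it — and for
how that machinery can misfire into chronic pain.

## The model

The belief `b = P(s = 1)` is a sufficient statistic for the observation
history. After observing `o` under a non-terminal action `a` with channel
`O(s, a, o)`:

```
b' = O(1, a, o) · b / (O(1, a, o) · b + O(0, a, o) · (1 − b))
```

One-step expected feedback on beliefs is `ρ(b, a) = b·r(1, a) + (1 − b)·r(0, a)`,
and the optimal value function solves the belief-MDP Bellman equation

```
V*(b) = max_a [ ρ(b, a) + γ Σ_o P(o | b, a) V*(b′(b, a, o)) ]
```

with terminal actions contributing `ρ` alone. `V*` is found by value
iteration on a uniform belief grid (step 0.01) with exact successor beliefs
and linear interpolation, and validated against an exact finite-horizon
expectimax tree on a small-support fixture. Observation channels are
discretised Gaussians on `{1, …, 100}`: high-information (HI; state means
15 apart, sd 15) and low-information (LI; 5 apart, sd 30).

Pain correlates: **phasic pain** `= Σ_s b(s) ζ(s, a)` (the belief-weighted
pain-system feedback of probing; `ζ(s, query) = r(s, query)`), **tonic
pain** `= b(s = 1)`.

## Worked example

```python
import painpomdp as pp

spec = pp.make_injury_pomdp()          # default 4-action model
V, Q = pp.value_iteration(spec)
print(pp.decision_thresholds(Q))       # (0.0, 0.94)
```

Solving the default model converges in 96 sweeps and yields commitment
thresholds `b_act = 0.00` and `b_rest = 0.94`: the agent defers and probes
at every intermediate belief. Simulating one episode with the true state
injured (`examples/simulate_one_episode.py`):

```
  t  belief  action  obs   feedback  phasic  tonic
  0   0.500  query     62      -4.0   -2.00  0.500
  1   0.690  query     76      -4.0   -2.76  0.690
  2   0.926  query     69      -4.0   -3.71  0.926
  3   0.978  rest       -     100.0    0.00  0.978

terminal action: rest; return +88.0; cumulative phasic pain -8.46
```

Each probe draws an observation from the injured channel, shifts the belief
upward, and hurts in proportion to the current injury belief; once the
belief crosses the rest threshold the agent commits correctly.

The `examples/` directory has one short script per capability: solving and
thresholds, belief-transition kernels (HI vs LI), single-episode traces,
information restriction, and aberrant-prior sweeps. The same experiments are
available from the shell:

```
painpomdp investigate --seed 1 --episodes 500 --out runs/investigation
painpomdp restrict --fast
painpomdp replay runs/investigation/manifest.json runs/replayed
```

Every run writes its resolved configuration, Q-tables, trajectory CSVs, a
summary JSON and a manifest from which `replay` reproduces all outputs
bit-exactly.

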