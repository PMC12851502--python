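# Methods

## Model

The package models a single decision-making episode about a hidden, static
binary injury state: `s = 0` (healthy) or `s = 1` (injured). The agent never
observes `s`; it holds a belief `b = P(s = 1)` and updates it by Bayes rule
from observations drawn through action-specific channels. Because the state
does not change within an episode, the belief is a martingale under its own
predictive distribution: the expected posterior equals the prior, only the
spread of the posterior depends on how informative the chosen channel is.

Actions are `act` and `rest` (terminal: the episode ends, the agent collects
`r(s, a)` once) and `query` and `null` (non-terminal: the agent collects
`r(s, a)`, draws one observation, and continues). Default utilities
(dimensionless feedback units):

| | act | rest | query | null |
|---|---|---|---|---|
| healthy (s=0) | +100 | −100 | 0 | −0.5 |
| injured (s=1) | −400 | +100 | −4 | −0.5 |

The asymmetry (−400 for acting while injured) encodes that aggravating a
real injury is far worse than resting unnecessarily. The `null` utility is
state-independent by construction (a minor opportunity cost).

Observation channels are Gaussians discretised onto the integer support
`{1, …, 100}` by integrating the density over unit bins `[o−½, o+½]` and
renormalising over the truncated support. Two information classes exist:
HI (state-conditional means 15 apart, sd 15; used by `query`) and LI (means
5 apart, sd 30; used by `null`). The means are placed symmetrically about
the support centre 50 with the injured state taking the higher mean; only
the separation matters for inference, and symmetry keeps updates unbiased
between states. Note that truncation pulls the LI channel's realised
moments noticeably toward the centre (realised sd ≈ 23.9 rather than 30);
the nominal parameters define the channel, the realised pmfs are what the
model uses everywhere.

Pain correlates: phasic pain of an action is `Σ_s b(s) ζ(s, a)`, where `ζ`
is the pain-system subset of the feedback table — by default only `query`
carries pain-system feedback, with `ζ(s, query) = r(s, query)`. Tonic pain
is the injury belief `b` itself. Both proportionality constants are 1, so
phasic pain reads on the utility scale and tonic pain on the belief scale.
Phasic pain is deliberately the belief-weighted *expectation*, not the
realised feedback: it is the agent's own constructed signal and is what the
cumulative-pain metrics sum over an episode.

## Solver

The POMDP is solved as a belief MDP on a uniform grid over `[0, 1]` with
step 0.01 (101 points including both endpoints). Value iteration starts
from `V0 ≡ 0` and repeats full Bellman backups until the sup-norm change
falls below `1e−6` (at most 10,000 sweeps; the default model converges in
96). Within a backup, successor beliefs are computed exactly and the value
function is evaluated by linear interpolation — consistent with the
piecewise-linear-and-convex structure of optimal POMDP value functions.
Discount `γ = 1`; convergence is guaranteed because terminal payoffs bound
the value while the strictly negative per-step deferral costs make infinite
deferral suboptimal. Likelihoods below `1e−300` are floored to zero;
a Bayes update conditioned on a zero-probability observation raises an
error naming the belief, action and observation.

Exact ties in the greedy policy are broken toward deferring actions
(`query > null > rest > act`) at interior grid points — the decision
thresholds are the most uncertain beliefs at which a terminal action first
wins, so deferral takes the boundary — but toward terminal actions at the
degenerate beliefs 0 and 1. The endpoint exception matters: at `b = 0`
probing is free (`r(0, query) = 0`) and uninformative, so `q(0, query)`
exactly ties `q(0, act) = +100` at the fixed point; an agent that deferred
on that tie would idle to the trial cap and realise 0 instead of +100.

**The simulated policy is grid-based.** `greedy_action` evaluates the
Q-function at the grid belief nearest to the current (exact) belief, so the
commitment regions are unions of grid cells. This is deliberate, and it is
load-bearing at the healthy end of the belief space: under the default
utilities the solved act-region of the *continuous* policy is exactly
`{b = 0}` (verified at grid steps down to 1e−4), a point exact Bayes
updates never reach, so a continuous-greedy agent that has in fact resolved
the state to near-certain health would defer forever and truncate. With the
grid policy, beliefs within half a grid step of 0 commit to `act` — the
behaviour the model is meant to produce. Beliefs recorded in traces remain
exact throughout; only the policy lookup snaps. Decision thresholds are
reported as grid beliefs for the same reason.

An exact finite-horizon expectimax over the full observation tree (no grid,
no interpolation) serves as an independent oracle. It is tractable on the
`tiny_obs` fixture (three actions, 5-point support, horizon 8; results
memoised on the belief since permuted observation sequences commute), and
the grid solution agrees with it within 0.16 utility units across the whole
grid — well inside the 0.5-unit band the validation test allows.

## Simulation

Episodes run the greedy policy from a starting belief `b0` with a fixed
true state: non-terminal steps collect `r(s_true, a)`, draw an observation
from the true-state channel, and update the belief; terminal actions end
the episode; episodes truncate after `max_trials = 100` non-terminal steps
(truncated episodes collect no terminal payoff and are counted separately,
never dropped). Per-episode random streams derive from
`numpy.random.SeedSequence(base_seed).spawn`, so batches are
bit-reproducible from the base seed and episodes are statistically
independent by construction.

Batch summaries average belief trajectories over trials 0…100, carrying
each episode's final belief forward after termination — the only
aggregation that keeps the average defined at every trial index —
both over all episodes and conditioned on the terminal action.

## Experiments

Four preconfigured runners (library functions; also exposed as thin CLI
subcommands). Defaults: 1000 episodes per condition (200 in `--fast`
mode), base seed 0, the utility/channel defaults above.

- **investigation** — three-action model (`null` omitted), `b0 = 0.5`,
  both true states. The solved thresholds are (0.00, 0.94); every episode
  begins with `query` and the terminal action tracks the true state.
- **factorial** — {HI, LI} × {query cost −4, −16}, no simulation needed:
  compares `q(0.5, query)` across cells and the kernel update magnitude
  `E|b′ − b|` at `b = 0.5` between channels.
- **info_restriction** — four-action model, true state healthy, `b0` at
  the midpoint of each condition's solved thresholds, query cost −4 vs
  −16. Reports belief-shift magnitudes, action usage, rest proportions and
  the first trial at which the mean belief falls below the resolution
  criterion 0.1 (configurable; chosen as an operational stand-in for a
  phenomenon otherwise defined only by trajectory plots).
- **aberrant_priors** — four-action model at cost −4; two sweeps of 8
  evenly spaced starting beliefs strictly inside (`b_act`, 1) with the
  state injured (cumulative phasic pain per `b0`) and inside (0, `b_rest`)
  with the state healthy (resolution time per `b0`); trends summarised by
  Spearman rank correlation.

Every run with an output directory writes its resolved config, Q-tables,
trajectory/trace CSVs (floats at 12 significant digits for bit-stable
reproduction), a summary JSON, and a manifest (config, parameters, seed,
solver metadata, file checksums) from which `experiments.replay` reproduces
all outputs byte-for-byte.

### A note on null-vs-query preference under dear probing

With the default `r(null) = −0.5` and infinite-horizon solving, raising the
query cost to −16 shrinks the deferral value but `null` becomes greedy only
on a narrow high-belief band (`b ∈ [0.75, 0.80]`, just below the rest
threshold); at the threshold-midpoint start the margin still favours
`query` (by ≈ 0.4 utility at `b ≈ 0.4`). The restriction experiment
therefore shows belief stalling, reduced probing and more maladaptive rest
commitments at −16 — but not wholesale substitution of `null` for `query`
at the start. A genuinely cost-free `null` would produce that substitution,
but it also makes infinite-horizon deferral free and the planning problem
degenerate (value iteration no longer converges), so the package keeps the
−0.5 opportunity cost.

## What the simulations do and do not show

The generator emulates the stylised conditions of the model itself —
static state, a single scalar observation channel, greedy behaviour under
a converged value function. Passing tests show the inference, planning and
metric machinery is correct under those conditions. They say nothing about
real interoception (multimodal, non-stationary, learned), actual recovery
dynamics (no state transitions), learning (no within- or across-episode
value updates, no exploration noise), or psychophysical pain scales (both
pain correlates are reported on model-internal scales with unit
proportionality constants).

## Known limitations

- Two hidden states only; the belief is a scalar.
- No transitions within episodes: recovery or worsening cannot occur
  mid-episode, so chronic-pain phenomena appear only as prolonged beliefs,
  not as mismatch with a changing body.
- Greedy policies only (no softmax/ε-exploration), matching the simulated
  behaviour the model analyses.
- Tonic pain is the belief `b`, not the value `V(b)`; the value-based
  alternative is a documented non-goal.
- Thresholds and commitment behaviour at the healthy end depend on the
  grid resolution through the grid-based policy (see Solver); the 0.01
  step is part of the model definition, not a numerical afterthought.
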