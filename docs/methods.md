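# Methods

`batbandit` models repeated binary feeder choices of foraging animals in a
two-armed bandit whose reward contingencies reverse — slowly (a stable
environment: the profitable side switches once, after two nights) or quickly
(a volatile environment: a reversal every hour, operationalised as every 13
trials, the empirical trials-per-hour rate).  One feeder pays with
probability 0.8, the other with 0.2.  This note documents the models, the
estimation and simulation procedures, the synthetic-data generator, and the
numerical and design choices behind them.

## Decision models

**Softmax Q-learning.**  Each action `i ∈ {a, b}` carries a value `Q_i`.
Choice follows the softmax policy

    P(a) = exp(β·Q_a) / (exp(β·Q_a) + exp(β·Q_b)),

with inverse temperature `β ≥ 0` (0 = value-blind random choice; large =
near-greedy).  After each trial the chosen action's value is updated by the
prediction error,

    Q_i(t+1) = Q_i(t) + α · (Reward(t) − Q_i(t)),       α ∈ [0, 1],

and the unchosen value is left untouched.  With rewards in {0, 1} and Q
initialised inside [0, 1], values remain in [0, 1] forever.

**Overnight carryover.**  Sessions are one animal-night; three assumptions
about what survives the day connect them:

* `reset` — Q restarts at (0, 0) each night (no overnight memory);
* `full` — Q carries over unchanged (perfect memory);
* `decay` — Q is scaled by `(1 − d)`, `d ∈ [0, 1]`, so `d = 1` is complete
  forgetting and `d = 0` full retention.

The direction of the decay multiplication is genuinely ambiguous in the
literature this design follows (the mechanical description and the verbal
interpretation point opposite ways); we adopt the forget convention
(`Q ← (1−d)·Q`, higher `d` = more forgetful) because it matches the verbal
interpretation and the direction of the reported group difference, and we
expose the alternative (`Q ← d·Q`) behind
`ModelSpec(decay_convention="retain")`.

**Choice perseveration.**  The perseveration variant adds a trace
`p_val ∈ [0, 1]` per action, initialised at (0.5, 0.5) at the start of each
night, and updated after every trial regardless of outcome:

    p_val ← (1 − p_rate) · p_val;   p_val(chosen) += p_rate,

so the chosen action's trace is pulled toward 1 and the other toward 0 at
rate `p_rate`.  The traces enter the policy as
`softmax(β·Q + p_exp·p_val)`; at `p_exp = 0` the model is exactly the plain
Q-learner (a nesting we verify to machine precision).  Traces are
re-initialised each night; only Q is subject to the carryover rule.

**Win-Stay-Lose-Shift (WSLS).**  A two-parameter stochastic rule: repeat a
rewarded choice with probability `p_stay`; leave an unrewarded one with
probability `p_shift`.  The first trial of each night has no predecessor
and is scored as probability 0.5.

## Likelihood and fitting

The per-animal negative log-likelihood accumulates `−ln P(observed
action)` across all trials of all nights, propagating latent state within a
night and applying the carryover rule between nights, with Q starting at
(0, 0) on night 1 for every variant (stated for the reset variant;
extended to all for comparability).  Probabilities are floored at 1e−12
inside the log so extreme parameter values cannot produce −∞.

Fitting is multi-start bounded maximum likelihood: L-BFGS-B within box
bounds (α, d, p_rate, p_stay, p_shift in [0, 1]; β in [0, 20]; p_exp in
[−10, 10]), `ftol` 1e−10, from 50 random starts by default.  Starts are
uniform within bounds except β, drawn log-uniformly on [0.01, 20] to cover
its scale; draws are per start, so a larger multi-start run extends a
smaller one under the same seed (which makes "more starts never worse" an
exact invariant).  The recovery experiments and model-recovery tests use
8–10 starts: with 2–3 box-bounded parameters on a smooth surface the
multi-start is saturated far below 50, and the smaller count keeps
experiment runtimes in seconds.  Models are compared per animal with
`BIC = k·ln(n) + 2·NLL` (and AIC = 2k + 2·NLL); the base Q-learner and
WSLS both have k = 2, so their log-likelihoods are also compared directly.

**Per-night fits.**  The decay variant can be fitted night by night,
yielding one (α, β, d) triple per night.  Night 1 starts from Q = (0, 0)
(its decay is undefined and reported as NaN).  For night k > 1 the previous
night's terminal Q is generated by replaying that night's own fitted
parameters, and the current night's free decay scales it:
`Q_start = (1 − d_k) · Q_end,k−1`.  Which parameters should generate the
inherited trajectory is an open design point; using each night's own fit is
the self-consistent choice and is recorded in the result metadata.

## Simulations

Schedules are piecewise-constant probability pairs, always a permutation of
(0.8, 0.2): the volatile schedule reverses every 13 trials; the stable
schedule alternates blocks of 251 and 214 trials (the empirical mean trial
counts before and after the experiment's single reversal), starting at the
beginning of a 251-block, with the final partial block truncated.

Agents are simulated choose → Bernoulli reward → update for 2000 trials
with no overnight forgetting (one continuous run).  The perseveration model
is deliberately not simulated.  The learning-rate grid search runs 108
agents per α in {0, 0.1, …, 1}; the β of each agent is cycled from a
supplied list (mirroring the reuse of a fixed set of per-animal empirical
values) or, by default, drawn uniformly from [1, 7] — a realistic range for
animals that are clearly but not deterministically value-guided; empirical
fits in this regime typically land inside it.  Two numerical-design points:

* *Common random numbers.*  Each agent's uniform stream is keyed on the
  agent index only and reused at every grid point, pairing the success
  estimates across learning rates.  The argmax of the mean-success curve
  then reflects the expected ordering rather than independent Monte-Carlo
  noise (the expected success difference between neighbouring grid points
  near the optimum is ~1e−3, below the independent-sampling SE at 108
  agents).
* *Seed ladder.*  Per-agent streams are spawned from the master seed, so
  increasing the agent count never reshuffles earlier agents.

The WSLS grid runs 100 simulations of 2000 trials per (p_stay, p_shift)
cell on the same schedules.  For validation there is an exact oracle,
`wsls_expected_success`: a WSLS agent's state is fully summarised by the
marginal probability of sitting on a given feeder, which obeys a linear
recursion over the schedule; iterating it gives the exact expected success
with no sampling.  For the pure strategy on the 13-trial schedule this
evaluates to (12·0.68 + 0.32)/13 ≈ 0.6523.

**Percentile test.**  An observed success rate is compared with a set of
simulated ones by strict empirical rank: flagged "low" ("high") only if its
rank from that end is ≤ 5% of the number of simulations (so rank 6 of 108
is not significant, since 0.05·108 = 5.4).

## Behavioural statistics

Trial extraction from raw landing logs: a landing is a new trial when the
feeder differs from the previous landing's, or when ≥ 3 s (inclusive) have
passed since the animal last left this same feeder; quicker same-feeder
re-landings merge into the existing trial and keep its original reward.
Overlapping landing intervals are rejected as corrupt input.

Success rate is the rewarded fraction of trials.  The reward effect is
`P(stay | previous rewarded) − P(stay | previous unrewarded)`, computed
over consecutive extracted trials within a night only (no cross-night
pairs); a condition with zero observations renders the effect undefined
rather than zero.  QC excludes (a) any night flagged as a hardware failure
together with all later nights of that animal, and (b) animals with a
negative reward effect on ≥ 3 of 4 nights (failure to learn), logging every
exclusion with its reason.  The night trend of the cohort's median reward
effect is a Pearson correlation against night number.

## Synthetic cohorts

The generator emulates the study design: 15 stable + 10 volatile animals,
4 nights each, per-night trial counts from a truncated normal (mean 120.3,
SD 59.2) floored at 20 trials so per-night fits stay defined.  Stable
animals keep one profitable side for nights 1–2 and the reversed side for
nights 3–4; volatile animals get 13-trial reversals within every night,
each night starting from the animal's assigned initial side.  Choices come
from a configurable agent — by default a decaying Q-learner whose true
parameters are drawn per animal from truncated normals matching the
reported group statistics (α: 0.22 ± 0.28 stable / 0.14 ± 0.17 volatile;
d: 0.33 ± 0.42 / 0.55 ± 0.41; β uniform on [1, 7]) — and every latent
parameter is recorded as JSON-round-trippable ground truth.

The landing-log expander produces land/leave timestamps with exponential
gaps on a fixed offset chosen so that genuine trials always clear the 3-s
rule, and can inject sub-3-s same-feeder re-landings that trial extraction
must merge away.  What the generator does *not* emulate: circadian activity
structure, wall-clock hourly reversals (the 13-trial equivalence stands in
for them), juice-volume dynamics, sensor noise beyond the re-landing
injections, and any within-animal parameter drift.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model class, not that real animals satisfy the model.

## Problem sizes and determinism

Default experiment sizes follow the study (50 starts, 108 agents × 2000
trials, 100 WSLS simulations); the test suite exercises the same code paths
at reduced sizes (e.g. 4–10 starts, 24–108 agents, 150–2000 trials) chosen
so the full suite completes in well under a minute while leaving every
full-size acceptance computation in place.  All randomness flows from
explicit integer seeds through `numpy` `SeedSequence` spawning; identical
seeds give byte-identical cohorts, fits and simulation curves.

## Known limitations

* Group-level inference (mixed models, t-tests, ANOVA) is out of scope; the
  package produces the per-animal inputs for such analyses.
* No standard errors or posterior uncertainty for the MLEs; recovery
  experiments quantify estimator quality instead.
* The decay convention is a modelling decision, not an empirical finding;
  both conventions are implemented.
* Per-night decay estimates for night 1 are undefined by construction.
* The volatile schedule treats "one hour" as exactly 13 trials; animals
  with atypical trial rates would blur reversal boundaries in real data.
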