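# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `metacontrol`. Everything quantitative
stated here is computed by the test suite or the example scripts; nothing
is quoted from external data.

## Task model

The environment is a two-stage decision task. Trials start in one of two
first-stage states, each owning two actions (spaceships, global ids 0–3;
state *s* owns 2*s* and 2*s*+1). Each action leads deterministically to one
of two planets; within a state the two actions always lead to different
planets (anti-correlated structure). Planet rewards are independent
reflected Gaussian random walks: a continuous latent value takes N(0, σ²)
steps (σ = 2 treasure units), is folded back at the bounds (x → 2·bound −
x, iterated), and is emitted rounded to the nearest integer in [0, 9].
Initial latent values are drawn uniformly over the integer bounds — the
design leaves them free, and a uniform draw is unbiased and reproducible.

Sessions default to 320 trials in four 80-trial blocks, alternating
stable/variable (stable first). Within every block exactly half the trials
are low-stakes and half high-stakes (×1 / ×5 points), counterbalanced over
the two start states (20 per cell); order is a seeded permutation. In
variable blocks, reversal events swap one state's two destinations; gaps
between events — and the gap from block start to the first event — are
uniform on [6, 14] trials, and the affected state is drawn uniformly
(which state swaps is not constrained by the design). Each trial also
randomizes which spaceship appears on the left (key 0) vs right (key 1).

Rather than shipping a fixed set of counterbalanced sequences, sequences
are generated from seeds with identical statistical structure; the cohort
generator cycles agents over four independently generated sequences to
mirror counterbalancing.

## Learner

State: first-stage values Q_MF(s, a) (4 entries), planet values Q_MF(p)
(2), transition beliefs T(p | s, a) (2×2×2, rows summing to 1), and the
previous trial's chosen spaceship and response key. Initialization: all
reward expectations at the midpoint of the reward bounds (4.5), all
transition entries at 0.5, no stickiness memory.

Per completed trial, in order: (1) choice probabilities from pre-trial
beliefs; (2) transition update — factual row toward the observed planet at
rate η, counterfactual row toward the complementary planet at rate η_CF
(the paired push/scale update conserves row sums exactly; the two rows
touched are distinct, so factual-then-counterfactual order is immaterial);
(3) SARSA(λ) reward update. η and η_CF are fixed at 1 in stable blocks and
free in variable blocks; η_CF = η in the default (single-rate) variant.

The choice rule is a softmax over Q_net = (1 − ω) Q_MF + ω Q_MB plus
π·rep(a) (1 if a was chosen on the previous trial — spaceship identity, so
rep = 0 for both actions when the start state differs) and ρ·resp(a) (1 if
a's key matches the previous key). Stickiness memory crosses block
boundaries and is retained through missed trials (the session runs
continuously; simplest stateful rule).

Missed responses: a first-stage miss contributes no likelihood term and no
updates. A second-stage miss contributes the first-stage likelihood term
and the transition update (the planet is displayed on arrival) but no
reward update. This is the literal reading of "informative about
transition-structure changes"; whether the stage-1 likelihood of such
trials should enter is ambiguous, and the behavior is centralized in the
likelihood so it can be revisited in one place.

Three implementations of the trial loop exist: the public single-step
operations (`model.py`), a numba kernel used by fitting/simulation
(`_kernel.py`), and a from-scratch brute-force oracle in the tests. The
suite asserts agreement to 1e-10, and that ω = 0 / ω = 1 reduce exactly to
independently coded pure model-free / model-based learners.

## Fitting

MAP estimation maximizes log-likelihood plus log-prior — Beta(2,2) on α,
λ, η, ω; Gamma on β; Normal(0,1) on π, ρ — on an unconstrained scale
(logit/log transforms) with the prior evaluated on the natural scale and no
Jacobian term, so the optimum is the natural-scale posterior mode.
Restarts (default 100; reducible) initialize from prior draws and run
L-BFGS with ftol 1e-6; the best run wins. The Gamma hyperparameters (3,
0.2) are read in the shape/scale convention (prior mode 0.4, sensible for
rewards on a 0–9 scale); the shape/rate reading (scale 5) is available via
`PriorSpec(beta_parameterization="rate")` since the convention is genuinely
ambiguous in the literature this prior comes from.

Variants: `standard` (10 parameters: four condition-wise ω, the rest
global), `dual_transition_rate` (11: adds a free η_CF), `exhaustive` (26:
α, λ, β, π, ρ, ω split by the four cells; η by stakes within variable
blocks). AIC = 2k − 2·log L with the likelihood evaluated at the MAP point
(no separate ML fit is run; with these weak priors the difference is
small, and the comparison is used relatively across variants fit the same
way).

Parameter recovery simulates agents at tabulated truths and refits them.
The recovery truth distribution is a design choice of this package: unit
parameters from Beta(2,2), stickiness from N(0, 0.5), and β from
Gamma(10, 0.175) (mean 1.75, sd ≈ 0.55). The β range encodes *engaged*
decision makers: as β → 0 choices approach coin flips and the strategy
weights become unidentifiable in principle, so a recovery study conditions
on value-guided behavior. At the study scale (50 agents × 320 trials, 20
restarts) the four ω recover with correlations typically 0.7–0.9; the
acceptance floor is set at 0.6, the pilot mean (≈ 0.75 for the weakest ω)
minus three pilot standard deviations. RMSE for every parameter drops by
roughly 1/√10 on tenfold longer sessions.

## Synthetic cohorts

Two groups ("younger", "older"), 50 agents each by default. Non-ω
parameters are drawn per group: α, λ ~ Beta(mean 0.5, concentration 6),
η ~ Beta(0.6, 6), β ~ Gamma(4, 0.2) (mean 0.8), π ~ N(0.2, 0.3),
ρ ~ N(0, 0.3) — mid-range values producing clearly value-guided but noisy
behavior. The four ω share a per-agent random tendency: a Beta(mean 0.5,
concentration 10) draw, plus per-cell planted shifts, plus N(0, 0.03)
jitter, clipped to (0, 1). The shifts are parameterized as effect-coded
regression coefficients (defaults: age 0.11, stakes 0.05, transition 0.04,
age×stakes 0.12, age×transition 0.09) so the generative model matches the
random-intercept regression used to analyze the fitted weights: condition
effects are stable within person, individual differences dominate between
persons.

Misses are injected uniformly at random at the group rates (defaults:
0.2% / 1.2% stage-1/stage-2 for younger, 1.6% / 2.1% for older),
independent of task state — the simplest null model for aborted trials.

Reaction times are synthetic plumbing, not a cognitive model: log rt2 =
base(group) + shift(group)·[revaluation trial] + vigor·E[reward] +
N(0, 0.25), with base log(600) / log(830) ms, shifts 0.15 / 0.06, and
vigor −0.01 per treasure unit; rt1 uses the base term only. These planted
values give the RT regression a known target (group slope ≈ log(830/600)
≈ 0.324, interaction ≈ −0.09). Real RT phenomena beyond this (fatigue,
heavy tails, post-error slowing) are deliberately absent, so passing RT
tests certifies the pipeline, not human realism.

## Analyses

*Baseline-corrected reward*: obtained reward minus the mean of the two
planets' current rewards, before stakes multiplication; missed trials are
excluded from the mean. *Revaluation trials*: per reversal event, the first
subsequent trial starting in the affected state with a valid first-stage
response; a second-stage miss does not block the flag (the planet is seen);
multiple reversals of one state before it is revisited collapse into a
single flag. *Performance matching*: mutual nearest neighbors across groups
on mean baseline-corrected reward, ties broken by lexicographically smaller
id (determinism), computed once on full-session means. *RT preprocessing*:
variable-block trials with a valid second-stage response and rt2 ≥ 200 ms
(strictly-below cutoff dropped); outcome log rt2; dummy codes (older = 1,
revaluation = 1). *Expectation covariate*: the learner is replayed at the
fitted parameters and the visited planet's pre-update value taken per
trial.

## Hierarchical regression

A Gaussian mixed model with by-participant random intercept and optional
random slopes, sampled by a conjugate Gibbs sampler: fixed coefficients
get N(0, (10·sd(y))²) priors, σ and each random-effect sd get
half-Cauchy(2.5·sd(y)) priors via the inverse-gamma scale-mixture
representation, making every full conditional standard. The outcome is
centered during sampling (the intercept is shifted back afterwards) so the
coefficient prior concerns deviations from the grand mean, and a
translation move resamples the likelihood-invariant direction between each
fixed coefficient and the mean of its matching random effects — without it
the centered parameterization mixes slowly. Four chains × 2000 iterations
(1000 warm-up) by default; R-hat and bulk ESS via arviz; if any reported
coefficient's ESS falls below 400 the model reruns once with doubled
iterations before being flagged unconverged. Coefficients are summarized
by posterior mean and the [.025, .975] percentile interval.

Effect coding (younger/older = ±0.5, high/low stakes = ±0.5,
stable/variable = ±0.5) is used for the ω analysis; dummy coding for the
revaluation RT analysis, where cell counts are unbalanced.

## Known limitations and phenomena

- **Differential shrinkage.** MAP ω estimates shrink toward the Beta(2,2)
  mode 0.5, and more strongly in variable blocks (where η is free and
  transitions are less certain) than in stable blocks. End to end this can
  bias the *transition* main effect of the fitted-ω regression slightly
  positive even when no effect is planted. The bias is group-symmetric and
  cancels in interactions with age, which is why the planted-zero
  calibration check targets the age×transition interaction; interval
  calibration of the regression itself is verified separately on directly
  simulated tables.
- Attenuation: planted ω coefficients come back sign-correct but shrunk
  (roughly 30–50% at 50 agents/group); analyses here are about signs and
  qualitative ordering, not unbiased effect-size estimation.
- The Gibbs sampler covers the Gaussian random-intercept/slope models used
  here; it is not a general-purpose regression engine (no GLMs, no
  crossed random effects, no correlated random-effect covariance).
- Problem sizes in the test suite (replication counts, restart counts,
  demo cohort sizes) are scaled to what the checks need statistically;
  the package defaults remain at the full study scale.
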