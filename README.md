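# metacontrol

Simulation and model-based analysis of *metacontrol* — how decision makers
arbitrate between a cheap, habit-like **model-free** strategy and a costly,
deliberative **model-based** strategy depending on what is at stake and how
stable the environment is.

The package implements, end to end and on fully synthetic cohorts:

- a **two-stage sequential decision task**: each trial starts in one of two
  first-stage states offering two spaceships; the chosen spaceship leads
  deterministically to a red or purple planet paying a drifting integer
  reward 0–9 (reflected Gaussian random walk, σ = 2). Sessions have 320
  trials in four alternating blocks — *stable* blocks, where the
  spaceship→planet mapping is fixed, and *variable* blocks, where one
  state's mapping reverses every 6–14 trials. A per-trial stakes cue
  converts treasure to points at ×1 (low) or ×5 (high);
- the **hybrid reinforcement-learning model** of behavior on this task;
- **MAP fitting** with the standard priors and random-restart scheme, model
  variants (10-, 11- and 26-parameter layouts), AIC comparison, parameter
  recovery and posterior predictive checks;
- the **downstream analyses**: baseline-corrected reward, mutual-nearest-
  neighbor performance matching, revaluation-trial identification,
  reaction-time preprocessing, and Bayesian hierarchical regressions;
- a **synthetic cohort generator** producing younger/older agent groups with
  planted, recoverable effects on the model-based weight and on reaction
  times.

## The model

A model-free learner updates cached values by SARSA(λ):

    δ₁ = Q_MF(s₂) − Q_MF(s₁, a₁)          δ₂ = r − Q_MF(s₂)
    Q_MF(s₁, a₁) ← Q_MF(s₁, a₁) + α δ₁ + α λ δ₂
    Q_MF(s₂)     ← Q_MF(s₂) + α δ₂

A model-based learner maintains transition beliefs T(s₂ | s₁, a₁), updated
from state prediction errors for the taken action (rate η, fixed at 1 in
stable blocks) and counterfactually for the untaken action (rate η_CF = η by
default, exploiting the anti-correlated structure), and plans

    Q_MB(s₁, a₁) = Σ_{s₂} T(s₂ | s₁, a₁) · Q_MF(s₂).

Choices follow a softmax over Q_net = (1 − ω) Q_MF + ω Q_MB with inverse
temperature β, choice stickiness π and response-key stickiness ρ. The
model-based weight ω ∈ [0, 1] is fitted separately for each (stakes ×
transition-condition) cell — four weights whose condition differences are
the metacontrol effects of interest. The standard layout has 10 free
parameters (α, λ, η, four ω, β, π, ρ); the exhaustive layout splits
everything by condition (26). Priors: Beta(2,2) on unit-interval
parameters, Gamma(3, 0.2) on β, Normal(0,1) on π and ρ; estimation is MAP
with 100 random restarts (configurable).

## Worked example

`examples/metacontrol_pipeline.py` simulates a 40-agent cohort with planted
effect-coded ω effects (age 0.11, stakes 0.05, transition 0.04, age×stakes
0.12, age×transition 0.09), MAP-fits every agent and regresses the fitted
weights on effect-coded predictors:

```
simulated 40 agents (20 per group), 320 trials each

hierarchical regression of fitted omega (converged: True):
     coefficient  mean  ci_low  ci_high  rhat      ess
       intercept 0.510   0.476    0.544 1.005 2825.309
             age 0.037  -0.028    0.102 1.002 1275.624
          stakes 0.016  -0.032    0.064 1.000 3262.539
      transition 0.023  -0.024    0.070 1.001 3904.703
    age_x_stakes 0.070  -0.027    0.162 1.001 4042.432
age_x_transition 0.064  -0.029    0.159 1.001 4242.760

performance matching: 13 mutual pairs, 14 unmatched
```

All planted coefficients come back with the right sign; magnitudes are
attenuated by estimation noise and prior shrinkage, and at this demo size
(20 per group) the intervals are wide — the test suite verifies sign
recovery systematically at 50 per group. The other example scripts
(`simulate_task.py`, `fit_single_agent.py`, `parameter_recovery.py`,
`revaluation_rt.py`) each demonstrate one capability and print a short
interpretation.

A thin CLI orchestrates the same stages against an output directory:

```bash
metacontrol run-all --config examples/run_config.yaml
metacontrol recover --config examples/run_config.yaml   # rerun one stage
```

producing `choices.csv`, `fits.csv`, `recovery.csv`, `ppc.csv`, regression
summaries and a JSON manifest with per-stage seeds.

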