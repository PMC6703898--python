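"""Synthetic agent cohorts with known ground truth.

Plays hybrid-model agents through generated task sequences to produce
behavioral datasets whose generating parameters are known, with planted
age-group and condition effects on the model-based weight, configurable
missed-response rates, and a log-normal reaction-time generator with a
revaluation-slowing effect. This gives every downstream stage (fitting,
regression, RT analysis) a recoverable ground truth.

Default cohort conditions mirror the study design: two groups ("younger",
"older"), four counterbalanced trial sequences, first-stage/second-stage miss
rates of 0.2%/1.2% (younger) and 1.6%/2.1% (older), and model-based-weight
effects on the effect-coded scale of 0.11 (age), 0.05 (stakes), 0.04
(transition stability), 0.12 (age x stakes) and 0.09 (age x transition).
The reaction-time generator is synthetic plumbing: a log-normal model whose
planted effects (group shift, revaluation slowing, reward-expectation vigor
slope) exist to give the RT regression something to recover, not to mimic
human RT distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._kernel import simulate_packed
from ._pack import pack_sequence, params_per_trial
from .model import ChoiceDataset, ModelParams, OMEGA_KEYS, TrialObservation
from .task import (
    CELL_ORDER, HIGH, LOW, STABLE, VARIABLE, TaskConfig, TrialSequence,
    generate_trial_sequence,
)

GROUPS = ("younger", "older")

#: effect-coded group levels (younger = +0.5, older = -0.5)
GROUP_CODE = {"younger": 0.5, "older": -0.5}
STAKES_CODE = {LOW: -0.5, HIGH: 0.5}
TRANSITION_CODE = {STABLE: 0.5, VARIABLE: -0.5}


def effect_coded_shifts(
    age: float = 0.11,
    stakes: float = 0.05,
    transition: float = 0.04,
    age_stakes: float = 0.12,
    age_transition: float = 0.09,
) -> dict:
    """Per-group, per-cell additive shifts of the mean model-based weight
    implied by effect-coded regression coefficients.

    With codes younger/older = +/-0.5, high/low stakes = +/-0.5 and
    stable/variable = +/-0.5, a cell's shift is the fitted value of the
    linear predictor at that cell (minus the intercept).
    """
    shifts: dict[str, dict[tuple[str, str], float]] = {}
    for g in GROUPS:
        a = GROUP_CODE[g]
        shifts[g] = {}
        for st, tr in CELL_ORDER:
            s, t = STAKES_CODE[st], TRANSITION_CODE[tr]
            shifts[g][(st, tr)] = (
                age * a + stakes * s + transition * t
                + age_stakes * a * s + age_transition * a * t
            )
    return shifts


def _default_param_dists() -> dict:
    dists = {
        "alpha": ("beta_mc", 0.5, 6.0),
        "lam": ("beta_mc", 0.5, 6.0),
        "eta": ("beta_mc", 0.6, 6.0),
        "beta": ("gamma", 4.0, 0.2),
        "pi": ("normal", 0.2, 0.3),
        "rho": ("normal", 0.0, 0.3),
        "omega_base": ("beta_mc", 0.5, 10.0),
    }
    return {g: dict(dists) for g in GROUPS}


@dataclass(frozen=True)
class RTGenSpec:
    """Log-normal reaction-time generator (synthetic plumbing).

    log rt2 = base_log_mean[group] + revaluation_shift[group] * reval
              + vigor_slope * expectation + N(0, log_sd); rt1 uses the base
    term and noise only. Units: log-milliseconds. Defaults plant a group
    difference of 0.32 log-ms, revaluation slowing of 0.15 (younger) vs 0.06
    (older), and a vigor slope of -0.01 per treasure unit.
    """

    base_log_mean: dict = field(
        default_factory=lambda: {"younger": float(np.log(600.0)),
                                 "older": float(np.log(830.0))}
    )
    log_sd: float = 0.25
    revaluation_shift: dict = field(
        default_factory=lambda: {"younger": 0.15, "older": 0.06}
    )
    vigor_slope: float = -0.01

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort (see module docstring for defaults)."""

    n_per_group: int = 50
    group_param_dists: dict = field(default_factory=_default_param_dists)
    planted_omega_effects: dict = field(default_factory=effect_coded_shifts)
    miss_rates: dict = field(
        default_factory=lambda: {"younger": (0.002, 0.012),
                                 "older": (0.016, 0.021)}
    )
    rt_model: RTGenSpec = field(default_factory=RTGenSpec)
    omega_concentration: float = 10.0
    omega_within_sd: float = 0.03
    n_sequences: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        for g, (m1, m2) in self.miss_rates.items():
            if not (0.0 <= m1 < 1.0 and 0.0 <= m2 < 1.0):
                raise ValueError(f"miss rates for {g} must lie in [0, 1)")
        for g, shifts in self.planted_omega_effects.items():
            base = self.group_param_dists[g]["omega_base"][1]
            for key, sh in shifts.items():
                if not 0.0 < base + sh < 1.0:
                    raise ValueError(
                        f"shifted omega mean {base + sh:.3f} for {g}/{key} "
                        "outside (0, 1)"
                    )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_param_dists)


def _draw(dist: tuple, rng: np.random.Generator) -> float:
    family = dist[0]
    if family == "beta_mc":  # Beta reparameterized by (mean, concentration)
        mean, conc = dist[1], dist[2]
        return float(rng.beta(mean * conc, (1.0 - mean) * conc))
    if family == "gamma":  # (shape, scale)
        return float(rng.gamma(dist[1], dist[2]))
    if family == "normal":
        return float(rng.normal(dist[1], dist[2]))
    raise ValueError(f"unknown distribution family {family!r}")


def draw_agent_params(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> ModelParams:
    """Draw one agent's true parameters from its group's distributions.

    The four model-based weights share a per-agent random tendency (a Beta
    draw around the group mean) on top of which the planted condition shifts
    act as stable within-person effects plus a small jitter
    (``omega_within_sd``) — the generative counterpart of the
    random-intercept structure the regression stage assumes.
    """
    dists = spec.group_param_dists[group]
    base_mean, conc = dists["omega_base"][1], spec.omega_concentration
    base = float(rng.beta(base_mean * conc, (1.0 - base_mean) * conc))
    omega = {}
    for key in OMEGA_KEYS:
        value = (
            base
            + spec.planted_omega_effects[group][key]
            + rng.normal(0.0, spec.omega_within_sd)
        )
        omega[key] = float(min(max(value, 1e-3), 1.0 - 1e-3))
    return ModelParams(
        alpha=_draw(dists["alpha"], rng),
        lam=_draw(dists["lam"], rng),
        eta=_draw(dists["eta"], rng),
        beta=max(_draw(dists["beta"], rng), 1e-6),
        pi=_draw(dists["pi"], rng),
        rho=_draw(dists["rho"], rng),
        omega=omega,
    )


def simulate_agent(
    params: ModelParams,
    sequence: TrialSequence,
    rng: np.random.Generator,
    miss1_rate: float = 0.0,
    miss2_rate: float = 0.0,
    participant_id: str = "sim",
    group: str = "synthetic",
    return_trace: bool = False,
):
    """Play one hybrid-model agent through a sequence.

    Choices are sampled from the model's choice rule with pre-trial beliefs;
    transitions resolve through the sequence's (possibly reversing) mapping;
    updates follow exactly the scheme the likelihood assumes, so with zero
    miss rates the generated data have a well-defined likelihood at the true
    parameters. Misses are injected uniformly at random.

    With ``return_trace`` also returns the per-trial second-stage reward
    expectation at arrival (the RT vigor covariate).
    """
    seq_arrays = pack_sequence(sequence)
    n = len(sequence)
    miss1 = rng.random(n) < miss1_rate
    miss2 = rng.random(n) < miss2_rate
    u = rng.random(n)
    lo, hi = sequence.config.reward_bounds
    par = params_per_trial(seq_arrays["cell"], seq_arrays["stable"], params)
    a_loc, planet, reward, q2v, _ = simulate_packed(
        seq_arrays["s1"], seq_arrays["key0"], seq_arrays["mapping"],
        seq_arrays["walks"], miss1, miss2, u, (lo + hi) / 2.0, *par,
    )
    observations = []
    for i, tr in enumerate(sequence.trials):
        if a_loc[i] < 0:
            observations.append(
                TrialObservation(tr, None, None, None, False, None)
            )
            continue
        a = 2 * tr.start_state + int(a_loc[i])
        made = reward[i] >= 0
        observations.append(
            TrialObservation(
                tr, a, tr.key_of(a), int(planet[i]), bool(made),
                int(reward[i]) if made else None,
            )
        )
    dataset = ChoiceDataset(participant_id, group, sequence, tuple(observations))
    if return_trace:
        return dataset, {"q2_visited": q2v}
    return dataset


def simulate_reaction_times(
    dataset: ChoiceDataset,
    spec: RTGenSpec,
    expectations: np.ndarray,
    rng: np.random.Generator,
) -> ChoiceDataset:
    """Fill rt1/rt2 (milliseconds) from the log-normal generator.

    ``expectations`` is the per-trial second-stage reward expectation
    (NaN on first-stage misses); revaluation trials are identified from the
    dataset's reversal schedule. Missed stages keep rt = None.
    """
    from .analysis import identify_revaluation_trials

    group = dataset.group
    base = spec.base_log_mean[group]
    shift = spec.revaluation_shift[group]
    reval = identify_revaluation_trials(dataset)
    new_obs = []
    for i, obs in enumerate(dataset.observations):
        if obs.miss1:
            new_obs.append(obs)
            continue
        rt1 = float(np.exp(base + rng.normal(0.0, spec.log_sd)))
        rt2 = None
        if not obs.miss2:
            mu = base + shift * float(reval[i]) + spec.vigor_slope * float(
                expectations[i]
            )
            rt2 = float(np.exp(mu + rng.normal(0.0, spec.log_sd)))
        new_obs.append(replace(obs, rt1=rt1, rt2=rt2))
    return replace_observations(dataset, tuple(new_obs))


def replace_observations(
    dataset: ChoiceDataset, observations: tuple
) -> ChoiceDataset:
    return ChoiceDataset(
        dataset.participant_id, dataset.group, dataset.sequence, observations
    )


def simulate_cohort(
    spec: CohortSpec, config: TaskConfig
) -> tuple[list[ChoiceDataset], pd.DataFrame]:
    """Simulate a full cohort: returns (datasets, ground-truth table).

    Agents cycle over ``n_sequences`` independently generated trial
    sequences (counterbalancing, as in the study design). The truth table
    has one row per agent with all generating parameters.
    """
    root = np.random.SeedSequence(spec.seed)
    seq_seeds, agent_seed = root.spawn(2)
    sequences = [
        generate_trial_sequence(config, np.random.default_rng(s))
        for s in seq_seeds.spawn(max(spec.n_sequences, 1))
    ]
    rng = np.random.default_rng(agent_seed)
    datasets: list[ChoiceDataset] = []
    rows = []
    idx = 0
    for group in spec.groups:
        m1, m2 = spec.miss_rates[group]
        for j in range(spec.n_per_group):
            params = draw_agent_params(spec, group, rng)
            pid = f"{group}_{j:03d}"
            seq = sequences[idx % len(sequences)]
            dataset, trace = simulate_agent(
                params, seq, rng, m1, m2, pid, group, return_trace=True
            )
            dataset = simulate_reaction_times(
                dataset, spec.rt_model, trace["q2_visited"], rng
            )
            datasets.append(dataset)
            row = {
                "participant": pid, "group": group,
                "alpha": params.alpha, "lam": params.lam, "eta": params.eta,
                "beta": params.beta, "pi": params.pi, "rho": params.rho,
            }
            for (st, tr), col in zip(
                OMEGA_KEYS, [f"omega_{s}_{c}" for s, c in OMEGA_KEYS]
            ):
                row[col] = params.omega[(st, tr)]
            rows.append(row)
            idx += 1
    columns = [
        "participant", "group", "alpha", "lam", "eta", "beta", "pi", "rho",
    ] + [f"omega_{s}_{c}" for s, c in OMEGA_KEYS]
    truth = pd.DataFrame(rows, columns=columns)
    return datasets, truth
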