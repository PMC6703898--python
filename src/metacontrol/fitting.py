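"""Maximum a posteriori estimation of the hybrid model.

Priors: Beta(2,2) on all unit-interval parameters (alpha, lam, eta, omega),
Gamma(shape 3, scale 0.2) on the inverse temperature beta, and standard
normal priors on the stickiness parameters pi and rho. The posterior is
maximized on an unconstrained scale (logit / log transforms) with the prior
evaluated on the natural scale, restarting the local optimizer from random
prior draws and keeping the best run.

Model variants:

- ``standard``: alpha, lam, eta, beta, pi, rho shared across conditions,
  omega split by the four (stakes, transition) cells -> 10 free parameters.
- ``exhaustive``: alpha, lam, beta, pi, rho and omega all split by the four
  cells, eta split by stakes within variable blocks -> 26 free parameters.
- ``dual_transition_rate``: standard plus a separate counterfactual
  transition rate eta_cf -> 11 free parameters.

Also provides AIC model comparison, parameter-recovery studies and posterior
predictive checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from ._kernel import loglik_packed
from ._pack import PackedDataset, pack_dataset, pack_sequence
from .model import ChoiceDataset, ModelParams, OMEGA_KEYS
from .task import CELL_ORDER, TaskConfig, generate_trial_sequence

_CELL_SUFFIX = [f"{s}_{c}" for s, c in CELL_ORDER]
#: stakes level of each condition cell (0 = low, 1 = high)
_CELL_STAKES = np.array([0, 1, 0, 1])


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the fitting priors.

    ``beta_parameterization`` selects whether (beta_shape, beta_scale) are
    read as Gamma(shape, scale) or Gamma(shape, rate); the default is the
    scale convention (prior mode 0.4 with the default hyperparameters).
    """

    unit_a: float = 2.0
    unit_b: float = 2.0
    beta_shape: float = 3.0
    beta_scale: float = 0.2
    beta_parameterization: str = "scale"
    stick_mean: float = 0.0
    stick_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_parameterization not in ("scale", "rate"):
            raise ValueError("beta_parameterization must be 'scale' or 'rate'")

    @property
    def _beta_scale_eff(self) -> float:
        if self.beta_parameterization == "scale":
            return self.beta_scale
        return 1.0 / self.beta_scale

    # closed-form log densities (scipy.stats is too slow in the inner loop)
    def logpdf_unit(self, x: float) -> float:
        if not 0.0 < x < 1.0:
            return -math.inf
        a, b = self.unit_a, self.unit_b
        lognorm = gammaln(a + b) - gammaln(a) - gammaln(b)
        return float(lognorm + (a - 1) * math.log(x) + (b - 1) * math.log1p(-x))

    def logpdf_pos(self, x: float) -> float:
        if x <= 0.0:
            return -math.inf
        k, th = self.beta_shape, self._beta_scale_eff
        return float(
            (k - 1) * math.log(x) - x / th - gammaln(k) - k * math.log(th)
        )

    def logpdf_real(self, x: float) -> float:
        z = (x - self.stick_mean) / self.stick_sd
        return float(
            -0.5 * z * z - math.log(self.stick_sd) - 0.5 * math.log(2 * math.pi)
        )

    def logpdf(self, kind: str, x: float) -> float:
        return {"unit": self.logpdf_unit,
                "pos": self.logpdf_pos,
                "real": self.logpdf_real}[kind](x)

    def sample(self, kind: str, rng: np.random.Generator) -> float:
        if kind == "unit":
            return float(rng.beta(self.unit_a, self.unit_b))
        if kind == "pos":
            return float(rng.gamma(self.beta_shape, self._beta_scale_eff))
        return float(rng.normal(self.stick_mean, self.stick_sd))


@dataclass(frozen=True)
class ModelVariant:
    """A free-parameter layout: ordered (name, kind) pairs with kind one of
    'unit', 'pos', 'real'."""

    name: str
    layout: tuple[tuple[str, str], ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.layout)


def _standard_layout() -> tuple:
    return (
        ("alpha", "unit"), ("lam", "unit"), ("eta", "unit"),
        *[(f"omega_{sfx}", "unit") for sfx in _CELL_SUFFIX],
        ("beta", "pos"), ("pi", "real"), ("rho", "real"),
    )


STANDARD = ModelVariant("standard", _standard_layout())
DUAL_TRANSITION_RATE = ModelVariant(
    "dual_transition_rate", _standard_layout() + (("eta_cf", "unit"),)
)
EXHAUSTIVE = ModelVariant(
    "exhaustive",
    tuple(
        (f"{base}_{sfx}", kind)
        for base, kind in (
            ("alpha", "unit"), ("lam", "unit"), ("omega", "unit"),
            ("beta", "pos"), ("pi", "real"), ("rho", "real"),
        )
        for sfx in _CELL_SUFFIX
    )
    + (("eta_low_variable", "unit"), ("eta_high_variable", "unit")),
)

VARIANTS = {v.name: v for v in (STANDARD, EXHAUSTIVE, DUAL_TRANSITION_RATE)}


def get_variant(name_or_variant) -> ModelVariant:
    if isinstance(name_or_variant, ModelVariant):
        return name_or_variant
    try:
        return VARIANTS[name_or_variant]
    except KeyError:
        raise ValueError(f"unknown model variant {name_or_variant!r}") from None


def count_free_params(variant) -> int:
    """Number of scalars optimized for a variant (standard: 10,
    exhaustive: 26, dual_transition_rate: 11)."""
    return len(get_variant(variant).layout)


def log_prior(values: dict, variant, priors: PriorSpec = PriorSpec()) -> float:
    """Sum of per-parameter log prior densities over the variant's free
    parameters; -inf (not an exception) outside the support."""
    variant = get_variant(variant)
    total = 0.0
    for name, kind in variant.layout:
        total += priors.logpdf(kind, float(values[name]))
        if total == -math.inf:
            return -math.inf
    return total


def expand_values(
    variant, values: dict, cell: np.ndarray, stable: np.ndarray
) -> tuple:
    """Per-trial parameter arrays for the kernels from a variant's values."""
    variant = get_variant(variant)
    n = cell.shape[0]

    def per_trial(base: str) -> np.ndarray:
        if base in values:
            return np.full(n, float(values[base]))
        per_cell = np.array([values[f"{base}_{sfx}"] for sfx in _CELL_SUFFIX])
        return per_cell[cell].astype(float)

    if "eta" in values:
        eta_var = np.full(n, float(values["eta"]))
    else:
        eta_by_stakes = np.array(
            [values["eta_low_variable"], values["eta_high_variable"]]
        )
        eta_var = eta_by_stakes[_CELL_STAKES[cell]].astype(float)
    eta_t = np.where(stable, 1.0, eta_var)
    if "eta_cf" in values:
        etacf_t = np.where(stable, 1.0, float(values["eta_cf"]))
    else:
        etacf_t = eta_t
    return (
        per_trial("alpha"), per_trial("lam"), eta_t, etacf_t,
        per_trial("omega"), per_trial("beta"), per_trial("pi"),
        per_trial("rho"),
    )


def values_to_model_params(values: dict) -> ModelParams | None:
    """ModelParams equivalent of a fitted value dict, when one exists
    (standard and dual-rate layouts; None for the exhaustive layout)."""
    try:
        return ModelParams(
            alpha=values["alpha"], lam=values["lam"], eta=values["eta"],
            beta=values["beta"], pi=values["pi"], rho=values["rho"],
            omega={
                key: values[f"omega_{sfx}"]
                for key, sfx in zip(OMEGA_KEYS, _CELL_SUFFIX)
            },
            eta_cf=values.get("eta_cf"),
        )
    except KeyError:
        return None


@dataclass
class FitResult:
    """Outcome of a MAP fit."""

    variant: ModelVariant
    values: dict
    log_posterior: float
    log_likelihood: float
    n_restarts: int
    best_restart_index: int
    converged_flags: np.ndarray
    participant_id: str = ""

    @property
    def params_hat(self) -> ModelParams | None:
        return values_to_model_params(self.values)

    @property
    def n_free_params(self) -> int:
        return len(self.variant.layout)


class FittingFailure(RuntimeError):
    """All optimizer restarts failed; carries per-restart diagnostics."""

    def __init__(self, diagnostics):
        super().__init__("all optimizer restarts failed")
        self.diagnostics = diagnostics


_EPS = 1e-9


def _to_unconstrained(kind: str, x: float) -> float:
    if kind == "unit":
        return float(logit(min(max(x, _EPS), 1.0 - _EPS)))
    if kind == "pos":
        return math.log(max(x, _EPS))
    return x


def _to_natural(kind: str, z: float) -> float:
    if kind == "unit":
        return float(expit(z))
    if kind == "pos":
        return math.exp(min(z, 30.0))
    return z


def fit_map(
    dataset: ChoiceDataset,
    variant=STANDARD,
    priors: PriorSpec = PriorSpec(),
    n_restarts: int = 100,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
) -> FitResult:
    """MAP estimate of the hybrid model for one participant.

    Runs ``n_restarts`` local optimizations (L-BFGS on an unconstrained
    reparameterization, initialized from prior draws) and keeps the run with
    the highest posterior. Deterministic given the generator state.
    """
    variant = get_variant(variant)
    if rng is None:
        rng = np.random.default_rng(0)
    packed = pack_dataset(dataset)
    if int((~packed.miss1).sum()) < 1:
        raise ValueError("dataset has no valid first-stage trials")
    kinds = [k for _, k in variant.layout]
    names = list(variant.names)

    def objective(z: np.ndarray) -> float:
        values = {
            n: _to_natural(k, float(zi)) for n, k, zi in zip(names, kinds, z)
        }
        lp = log_prior(values, variant, priors)
        if lp == -math.inf:
            return 1e12
        arrays = expand_values(variant, values, packed.cell, packed.stable)
        ll = loglik_packed(*packed.arrays(), *arrays)
        if math.isnan(ll):
            return 1e12
        return -(ll + lp)

    best = None
    best_idx = -1
    flags = np.zeros(n_restarts, dtype=bool)
    diagnostics = []
    for i in range(n_restarts):
        x0 = np.array(
            [_to_unconstrained(k, priors.sample(k, rng)) for k in kinds]
        )
        try:
            res = minimize(
                objective, x0, method="L-BFGS-B",
                options={"ftol": tol, "gtol": 1e-8},
            )
        except FloatingPointError as exc:  # pragma: no cover - defensive
            diagnostics.append(str(exc))
            continue
        flags[i] = bool(res.success)
        diagnostics.append(res.message)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
            best_idx = i
    if best is None:
        raise FittingFailure(diagnostics)

    values = {
        n: _to_natural(k, float(zi))
        for n, k, zi in zip(names, kinds, best.x)
    }
    lp = log_prior(values, variant, priors)
    arrays = expand_values(variant, values, packed.cell, packed.stable)
    ll = float(loglik_packed(*packed.arrays(), *arrays))
    return FitResult(
        variant=variant,
        values=values,
        log_posterior=ll + lp,
        log_likelihood=ll,
        n_restarts=n_restarts,
        best_restart_index=best_idx,
        converged_flags=flags,
        participant_id=dataset.participant_id,
    )


def aic(fit: FitResult) -> float:
    """Akaike information criterion, 2k - 2 log L, with the likelihood
    evaluated at the MAP point."""
    return 2.0 * fit.n_free_params - 2.0 * fit.log_likelihood


def fit_cohort(
    datasets,
    variant=STANDARD,
    priors: PriorSpec = PriorSpec(),
    n_restarts: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit every dataset; returns fits plus a tidy summary table."""
    variant = get_variant(variant)
    if rng is None:
        rng = np.random.default_rng(0)
    fits = []
    rows = []
    for ds in datasets:
        fit = fit_map(ds, variant, priors, n_restarts, rng)
        fits.append(fit)
        row = {"participant": ds.participant_id, "group": ds.group,
               "variant": variant.name}
        row.update(fit.values)
        row.update(
            log_posterior=fit.log_posterior,
            log_likelihood=fit.log_likelihood, aic=aic(fit),
        )
        rows.append(row)
    return fits, pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Per-parameter recovery quality from a simulate-and-refit study."""

    table: pd.DataFrame  # parameter, correlation, bias, rmse, degenerate
    n_agents: int
    config_summary: dict = field(default_factory=dict)

    def correlation(self, parameter: str) -> float:
        row = self.table.loc[self.table["parameter"] == parameter]
        return float(row["correlation"].iloc[0])


def recovery_truth_table(
    n_agents: int,
    rng: np.random.Generator,
    variant=STANDARD,
    beta_dist: tuple[float, float] = (10.0, 0.175),
    stick_sd: float = 0.5,
) -> pd.DataFrame:
    """True-parameter table for a recovery study.

    Unit-interval parameters are drawn from Beta(2,2) (the full plausible
    range); stickiness from a zero-mean normal; the inverse temperature from
    a Gamma with default mean 1.75 (shape 10, scale 0.175). The beta range
    represents engaged decision makers: agents whose choices are close to
    random carry almost no information about their strategy weights, so a
    recovery study conditions on value-guided behavior.
    """
    variant = get_variant(variant)
    rows = []
    for i in range(n_agents):
        row = {"participant": f"rec_{i:03d}"}
        for name, kind in variant.layout:
            if kind == "unit":
                row[name] = float(rng.beta(2.0, 2.0))
            elif kind == "pos":
                row[name] = float(rng.gamma(*beta_dist))
            else:
                row[name] = float(rng.normal(0.0, stick_sd))
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_recovery(
    truth_table: pd.DataFrame,
    config: TaskConfig,
    variant=STANDARD,
    priors: PriorSpec = PriorSpec(),
    rng: np.random.Generator | None = None,
    n_restarts: int = 20,
    n_sequences: int = 4,
) -> RecoveryReport:
    """Simulate agents at the tabulated true parameters, refit them, and
    report correlation / bias / RMSE per free parameter.

    Zero-variance truths yield an undefined correlation (NaN) flagged as
    degenerate. Truth columns must carry the variant's parameter names
    (``eta_cf`` missing from the table defaults to ``eta``).
    """
    from .cohorts import simulate_agent

    variant = get_variant(variant)
    if rng is None:
        rng = np.random.default_rng(0)
    sequences = [
        generate_trial_sequence(config, rng) for _ in range(n_sequences)
    ]
    estimates = {name: [] for name in variant.names}
    for i, row in truth_table.reset_index(drop=True).iterrows():
        values = {n: float(row[n]) for n in variant.names if n in row}
        if "eta_cf" in variant.names and "eta_cf" not in values:
            values["eta_cf"] = values["eta"]
        params = values_to_model_params(values)
        if params is None:
            raise ValueError(
                "parameter_recovery requires a ModelParams-compatible layout"
            )
        ds = simulate_agent(
            params, sequences[i % len(sequences)], rng,
            participant_id=f"rec_{i:03d}",
        )
        fit = fit_map(ds, variant, priors, n_restarts, rng)
        for name in variant.names:
            estimates[name].append((values[name], fit.values[name]))

    rows = []
    for name in variant.names:
        true, est = np.array(estimates[name]).T
        degenerate = bool(np.std(true) < 1e-12 or np.std(est) < 1e-12)
        corr = (
            float(np.corrcoef(true, est)[0, 1]) if not degenerate else np.nan
        )
        rows.append(
            {
                "parameter": name,
                "correlation": corr,
                "bias": float(np.mean(est - true)),
                "rmse": float(np.sqrt(np.mean((est - true) ** 2))),
                "degenerate": degenerate,
            }
        )
    return RecoveryReport(
        table=pd.DataFrame(rows),
        n_agents=len(truth_table),
        config_summary={
            "n_trials": config.n_trials, "variant": variant.name,
            "n_restarts": n_restarts,
        },
    )


def recovery_from_fits(
    truth_table: pd.DataFrame,
    fit_frame: pd.DataFrame,
    variant=STANDARD,
) -> RecoveryReport:
    """Recovery summary comparing a truth table against already-computed fits
    of the same (simulated) participants, matched on the participant column."""
    variant = get_variant(variant)
    merged = truth_table.merge(
        fit_frame, on="participant", suffixes=("_true", "_est")
    )
    rows = []
    for name in variant.names:
        t_col = f"{name}_true" if f"{name}_true" in merged else name
        e_col = f"{name}_est"
        if e_col not in merged:
            continue
        true = merged[t_col].to_numpy(float)
        est = merged[e_col].to_numpy(float)
        degenerate = bool(np.std(true) < 1e-12 or np.std(est) < 1e-12)
        rows.append(
            {
                "parameter": name,
                "correlation": (
                    float(np.corrcoef(true, est)[0, 1])
                    if not degenerate else np.nan
                ),
                "bias": float(np.mean(est - true)),
                "rmse": float(np.sqrt(np.mean((est - true) ** 2))),
                "degenerate": degenerate,
            }
        )
    return RecoveryReport(
        table=pd.DataFrame(rows),
        n_agents=len(merged),
        config_summary={"variant": variant.name, "source": "existing fits"},
    )


def _repeat_rate(packed: PackedDataset) -> float:
    """Fraction of consecutive valid same-start-state trial pairs on which
    the same spaceship was chosen."""
    s1, a = packed.s1, packed.a_loc
    valid = ~packed.miss1
    pairs = rep = 0
    prev = None
    for t in range(len(s1)):
        if not valid[t]:
            continue
        cur = (int(s1[t]), int(a[t]))
        if prev is not None and prev[0] == cur[0]:
            pairs += 1
            rep += prev[1] == cur[1]
        prev = cur
    return rep / pairs if pairs else math.nan


def posterior_predictive(
    fit: FitResult,
    dataset: ChoiceDataset,
    n_sims: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Posterior predictive check of one participant's fit.

    Simulates ``n_sims`` sessions at the MAP parameters on the participant's
    own trial sequence and compares summary statistics (per-cell mean
    baseline-corrected reward; first-stage repeat rate) between the observed
    data and the 2.5-97.5% simulation interval.
    """
    from .analysis import baseline_corrected_reward
    from .cohorts import simulate_agent

    if rng is None:
        rng = np.random.default_rng(0)
    seq = dataset.sequence
    seq_arrays = pack_sequence(seq)
    cell = seq_arrays["cell"]

    def stats(ds: ChoiceDataset) -> dict:
        per_trial, _ = baseline_corrected_reward(ds)
        out = {}
        for i, (s, c) in enumerate(CELL_ORDER):
            vals = per_trial[(cell == i) & ~np.isnan(per_trial)]
            out[f"bc_reward_{s}_{c}"] = (
                float(np.mean(vals)) if len(vals) else math.nan
            )
        out["repeat_rate"] = _repeat_rate(pack_dataset(ds))
        return out

    observed = stats(dataset)
    params = fit.params_hat
    if params is None:
        raise ValueError("posterior_predictive requires a standard-layout fit")
    sims = []
    for _ in range(n_sims):
        sims.append(stats(simulate_agent(params, seq, rng)))
    sim_frame = pd.DataFrame(sims)
    rows = []
    for stat in observed:
        col = sim_frame[stat].dropna()
        rows.append(
            {
                "statistic": stat,
                "observed": observed[stat],
                "sim_mean": float(col.mean()),
                "sim_lo": float(col.quantile(0.025)),
                "sim_hi": float(col.quantile(0.975)),
            }
        )
    return pd.DataFrame(rows)
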