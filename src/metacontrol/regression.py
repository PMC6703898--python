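"""Bayesian hierarchical linear regression for behavioral tables.

Gaussian-likelihood mixed model with a by-participant random intercept and
optional random slopes for within-subject predictors:

    y_ij = x_ij' b + z_ij' u_i + e_ij,   e_ij ~ N(0, sigma^2)
    u_i ~ N(0, diag(tau_1^2, ..., tau_q^2))

Priors are weakly informative: N(0, (10 sd(y))^2) on every fixed
coefficient, half-Cauchy(2.5 sd(y)) on sigma and on each random-effect
standard deviation. Because the half-Cauchy admits an inverse-gamma scale
mixture representation, the full conditional of every block is conjugate and
the posterior is sampled with a Gibbs sampler: four independent chains of
2000 iterations, the first 1000 discarded as warm-up. Convergence is
assessed with the Gelman-Rubin statistic (R-hat < 1.1) and the effective
sample size of reported coefficients (>= 400); when the ESS criterion fails
the chains are rerun once with twice the iterations before the result is
flagged as unconverged.

Coefficients are summarized by their marginal posterior mean and the
[.025, .975] percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RegressionSpec:
    """Contract of one hierarchical regression.

    ``predictors`` are column names of the (already numerically coded)
    analysis table; ``random_slopes`` must be a subset of them. An intercept
    (fixed, and random by participant) is always included.
    """

    outcome: str
    predictors: tuple[str, ...]
    group_col: str = "participant"
    random_slopes: tuple[str, ...] = ()
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    coef_prior_scale_mult: float = 10.0
    variance_prior_scale_mult: float = 2.5
    rhat_threshold: float = 1.1
    ess_threshold: float = 400.0

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        missing = set(self.random_slopes) - set(self.predictors)
        if missing:
            raise ValueError(f"random slopes not among predictors: {missing}")


@dataclass
class RegressionResult:
    """Posterior summaries per coefficient plus convergence diagnostics."""

    table: pd.DataFrame  # coefficient, mean, ci_low, ci_high, rhat, ess
    converged: bool
    iterations_used: int
    sigma_mean: float
    tau_mean: dict = field(default_factory=dict)

    def coef(self, name: str) -> pd.Series:
        return self.table.set_index("coefficient").loc[name]


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape, 1.0)


def _run_chain(
    rng: np.random.Generator,
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    iterations: int,
    s_b: float,
    a_hc: float,
    z_to_x: np.ndarray,
) -> dict:
    n, p = X.shape
    q = Z.shape[1]
    XtX = X.T @ X

    b = np.zeros(p)
    u = np.zeros((n_groups, q))
    sigma2 = max(float(np.var(y)), 1e-6)
    tau2 = np.full(q, sigma2)
    a_sig = 1.0
    a_tau = np.ones(q)

    # per-group Z'Z blocks, fixed across iterations
    ZtZ = np.zeros((n_groups, q, q))
    for k in range(q):
        for l in range(q):
            ZtZ[:, k, l] = np.bincount(gidx, Z[:, k] * Z[:, l], n_groups)

    draws_b = np.empty((iterations, p))
    draws_sigma = np.empty(iterations)
    draws_tau = np.empty((iterations, q))
    eye_p = np.eye(p)
    for it in range(iterations):
        zu = np.einsum("ij,ij->i", Z, u[gidx])

        # fixed effects
        ystar = y - zu
        prec = XtX / sigma2 + eye_p / s_b**2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ ystar / sigma2)
        b = mean + np.linalg.solve(chol.T, rng.standard_normal(p))

        # random effects, all groups at once
        r = y - X @ b
        Ztr = np.stack(
            [np.bincount(gidx, Z[:, k] * r, n_groups) for k in range(q)],
            axis=1,
        )
        prec_u = ZtZ / sigma2 + np.diag(1.0 / tau2)
        chol_u = np.linalg.cholesky(prec_u)
        mean_u = np.linalg.solve(prec_u, Ztr[..., None] / sigma2)[..., 0]
        noise = rng.standard_normal((n_groups, q, 1))
        u = mean_u + np.linalg.solve(
            np.transpose(chol_u, (0, 2, 1)), noise
        )[..., 0]

        # translation move: shift mass between each fixed coefficient and
        # the mean of its matching random effects (likelihood-invariant
        # direction; sampling along it breaks the slow mixing of the
        # centered parameterization)
        for k in range(q):
            j = z_to_x[k]
            prec_c = 1.0 / s_b**2 + n_groups / tau2[k]
            mean_c = (-b[j] / s_b**2 + u[:, k].sum() / tau2[k]) / prec_c
            c = mean_c + rng.standard_normal() / np.sqrt(prec_c)
            b[j] += c
            u[:, k] -= c

        # variance components (half-Cauchy via inverse-gamma mixture)
        for k in range(q):
            tau2[k] = _inv_gamma(
                rng, (n_groups + 1.0) / 2.0,
                1.0 / a_tau[k] + 0.5 * float(u[:, k] @ u[:, k]),
            )
            a_tau[k] = _inv_gamma(rng, 1.0, 1.0 / a_hc**2 + 1.0 / tau2[k])
        resid = y - X @ b - np.einsum("ij,ij->i", Z, u[gidx])
        sigma2 = _inv_gamma(
            rng, (n + 1.0) / 2.0, 1.0 / a_sig + 0.5 * float(resid @ resid)
        )
        a_sig = _inv_gamma(rng, 1.0, 1.0 / a_hc**2 + 1.0 / sigma2)

        draws_b[it] = b
        draws_sigma[it] = np.sqrt(sigma2)
        draws_tau[it] = np.sqrt(tau2)
    return {"b": draws_b, "sigma": draws_sigma, "tau": draws_tau}


def _sample(
    table: pd.DataFrame,
    spec: RegressionSpec,
    rng: np.random.Generator,
    iterations: int,
) -> tuple[pd.DataFrame, dict]:
    y = table[spec.outcome].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(table))]
        + [table[c].to_numpy(float) for c in spec.predictors]
    )
    Z = np.column_stack(
        [np.ones(len(table))]
        + [table[c].to_numpy(float) for c in spec.random_slopes]
    )
    groups, gidx = np.unique(table[spec.group_col].to_numpy(), return_inverse=True)
    sd_y = max(float(np.std(y)), 1e-3)
    s_b = spec.coef_prior_scale_mult * sd_y
    a_hc = spec.variance_prior_scale_mult * sd_y
    # sample with the outcome centered so the coefficient prior is about
    # deviations from the grand mean, then shift the intercept back
    mean_y = float(np.mean(y))
    y_c = y - mean_y
    z_to_x = np.array(
        [0] + [1 + list(spec.predictors).index(s) for s in spec.random_slopes]
    )

    names = ["intercept"] + list(spec.predictors)
    warm = spec.warmup * iterations // spec.iterations
    chains = [
        _run_chain(
            np.random.default_rng(rng.integers(2**31)),
            y_c, X, Z, gidx, len(groups), iterations, s_b, a_hc, z_to_x,
        )
        for _ in range(spec.chains)
    ]
    post_b = np.stack([c["b"][warm:] for c in chains])  # (chain, draw, p)
    post_b[:, :, 0] += mean_y
    idata = az.from_dict(posterior={"b": post_b})
    rhat = az.rhat(idata)["b"].values
    ess = az.ess(idata)["b"].values

    flat = post_b.reshape(-1, post_b.shape[-1])
    rows = []
    for j, name in enumerate(names):
        rows.append(
            {
                "coefficient": name,
                "mean": float(flat[:, j].mean()),
                "ci_low": float(np.quantile(flat[:, j], 0.025)),
                "ci_high": float(np.quantile(flat[:, j], 0.975)),
                "rhat": float(rhat[j]),
                "ess": float(ess[j]),
            }
        )
    sigma = float(np.concatenate([c["sigma"][warm:] for c in chains]).mean())
    tau = np.concatenate([c["tau"][warm:] for c in chains]).mean(axis=0)
    tau_names = ["intercept"] + list(spec.random_slopes)
    extras = {
        "sigma": sigma,
        "tau": {n: float(t) for n, t in zip(tau_names, tau)},
    }
    return pd.DataFrame(rows), extras


def fit_hierarchical_lm(
    table: pd.DataFrame,
    spec: RegressionSpec,
    rng: np.random.Generator | None = None,
) -> RegressionResult:
    """Fit the hierarchical model to an analysis table.

    Reruns once with doubled iterations if any reported coefficient's ESS
    falls below the threshold; the result's ``converged`` flag is True only
    when all R-hat values are below the threshold and all reported-
    coefficient ESS values reach it.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    missing = {spec.outcome, *spec.predictors, spec.group_col} - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    if not len(table):
        raise ValueError("empty analysis table")

    iterations = spec.iterations
    summary, extras = _sample(table, spec, rng, iterations)
    if (summary["ess"] < spec.ess_threshold).any():
        iterations *= 2
        summary, extras = _sample(table, spec, rng, iterations)
    converged = bool(
        (summary["rhat"] < spec.rhat_threshold).all()
        and (summary["ess"] >= spec.ess_threshold).all()
    )
    return RegressionResult(
        table=summary,
        converged=converged,
        iterations_used=iterations,
        sigma_mean=extras["sigma"],
        tau_mean=extras["tau"],
    )
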