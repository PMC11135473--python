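"""Bayesian multi-kernel regression fitted by Gibbs sampling.

The observation model is

    y = mu + sum_k u_k + X beta + eps,
    u_k ~ N(0, sigma_k^2 K_k),   beta ~ N(0, sigma_beta^2 I),
    eps ~ N(0, sigma^2 I),

where each K_k is an observation-level kernel (environment, genotype, or
their Hadamard interaction) and the optional ``beta`` block carries the
selected environmental covariates under a Bayesian ridge regression prior
(i.i.d. Gaussian coefficients with a common variance).

Sampling strategy
-----------------
Each kernel is eigendecomposed once, K = V D V'; eigenvalues below
``1e-10 * lambda_max`` are truncated.  Writing u_k = Phi_k delta_k with
Phi_k = V sqrt(D) turns the kernel term into a Gaussian regression on
orthogonal columns (Phi' Phi = D), so the full conditional of delta_k
factorizes and the whole block is drawn jointly in O(n r) per sweep.
Variance components get scaled-inverse-chi-square full conditionals with
prior degrees of freedom ``prior_df``.  Prior scales follow the convention
of the reference Bayesian ridge/RKHS software: the explained-variance
budget ``prior_R2 * var(y_obs)`` is split equally across model terms and
each term's prior mode is set on the scale its design implies — divided by
the kernel's mean diagonal for kernel terms, and by the summed column
variance of the covariate block for the ridge coefficients.  The residual
prior mode is ``(1 - prior_R2) * var(y_obs)``.  The intercept has a flat prior.  Missing
responses are imputed by data augmentation each sweep, so held-out rows
participate in the kernels but carry no likelihood information.

``y_hat`` is the posterior mean of the linear predictor (no residual draw)
over the kept samples; results are deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .io_data import ValidationError
from .kernels import KernelMatrix

__all__ = ["ModelSpec", "MCMCConfig", "FitResult", "fit", "predict_missing", "variance_report"]

PREDICTORS = ("E+G", "E+G+GE", "E+G+BRR", "E+G+GE+BRR")
STRATEGIES = ("NoEC", "EC", "FE")

EIG_TRUNC = 1e-10


@dataclass
class MCMCConfig:
    """Gibbs chain settings and the shared variance prior.

    ``fixed_variances`` pins named components ('E', 'g', 'gE', 'beta',
    'resid') at given values instead of sampling them — used for validation
    against closed-form mixed-model solutions.
    """

    n_iter: int = 10000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_R2: float = 0.5
    fixed_variances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValidationError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


@dataclass
class ModelSpec:
    """Which kernels and covariate block enter the linear predictor.

    ``kernels`` maps term names to observation-level kernels (e.g.
    {'E': ..., 'g': ..., 'gE': ...}); ``brr_covariates`` is the
    observation-expanded matrix of selected standardized covariates for the
    BRR predictors, or None.
    """

    predictor: str
    strategy: str
    kernels: dict[str, KernelMatrix]
    brr_covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise ValidationError(
                f"unknown predictor {self.predictor!r}; valid: {PREDICTORS}"
            )
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; valid: {STRATEGIES}"
            )
        include_ge = "GE" in self.predictor
        if include_ge != ("gE" in self.kernels):
            raise ValidationError("GE predictors require (exactly) a 'gE' kernel term")
        if "BRR" not in self.predictor and self.brr_covariates is not None:
            raise ValidationError(f"{self.predictor} takes no covariate block")
        labels = None
        for K in self.kernels.values():
            if labels is None:
                labels = K.labels
            elif K.labels != labels:
                raise ValidationError("kernel terms have mismatched observation labels")

    @property
    def include_ge(self) -> bool:
        return "GE" in self.predictor


@dataclass
class FitResult:
    """Posterior summaries of one model fit."""

    mu_hat: float
    var_components: dict[str, float]
    effects: dict[str, np.ndarray]
    y_hat: np.ndarray
    samples_kept: int
    obs_keys: list
    predictor: str
    strategy: str
    n_missing: int
    y_obs_mean: float
    diagnostics: dict[str, float] = field(default_factory=dict)


def _split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction from splitting one chain in half."""
    m = len(x) // 2
    if m < 5:
        return float("nan")
    halves = np.stack([x[:m], x[m : 2 * m]])
    within = halves.var(axis=1, ddof=1).mean()
    between = m * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    var_plus = (m - 1) / m * within + between / m
    return float(np.sqrt(var_plus / within))


def fit(spec: ModelSpec, y: np.ndarray, mcmc: MCMCConfig) -> FitResult:
    """Run the Gibbs sampler and return posterior means.

    ``y`` is the response vector aligned with the kernels' observation
    labels; NaN entries are treated as unknown (prediction targets).
    """
    y = np.asarray(y, dtype=float)
    labels = next(iter(spec.kernels.values())).labels
    n = len(labels)
    if y.shape != (n,):
        raise ValidationError("response length does not match kernel labels")
    obs = np.isfinite(y)
    if not obs.any():
        raise ValidationError("need at least one non-missing response")

    rng = np.random.default_rng(mcmc.seed)
    fixed = mcmc.fixed_variances
    df0 = mcmc.prior_df
    var_y = float(np.var(y[obs], ddof=1)) if obs.sum() > 1 else 1.0
    var_y = max(var_y, 1e-12)

    terms = list(spec.kernels)
    X = spec.brr_covariates
    has_brr = X is not None and X.shape[1] > 0
    if has_brr:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise ValidationError("covariate block rows do not match observations")
        XtX = X.T @ X
        q = X.shape[1]
    n_terms = len(terms) + (1 if has_brr else 0)

    budget = mcmc.prior_R2 * var_y / max(n_terms, 1)  # per-term explained variance
    S0_e = (1.0 - mcmc.prior_R2) * var_y * (df0 + 2.0) / df0

    Phi: dict[str, np.ndarray] = {}
    d_eig: dict[str, np.ndarray] = {}
    S0_u: dict[str, float] = {}
    for name, K in spec.kernels.items():
        w, V = np.linalg.eigh(K.values)
        lam_max = max(float(w[-1]), 0.0)
        keep = w > EIG_TRUNC * max(lam_max, 1e-300)
        Phi[name] = V[:, keep] * np.sqrt(w[keep])
        d_eig[name] = w[keep]
        mean_diag = max(float(np.mean(np.diag(K.values))), 1e-12)
        S0_u[name] = budget / mean_diag * (df0 + 2.0) / df0
    if has_brr:
        msx = max(float(X.var(axis=0, ddof=1).sum()), 1e-12)
        S0_beta = budget / msx * (df0 + 2.0) / df0

    mu = float(np.mean(y[obs]))
    y_cur = y.copy()
    y_cur[~obs] = mu
    delta = {name: np.zeros(len(d_eig[name])) for name in terms}
    beta = np.zeros(q) if has_brr else None
    sig2_u = {
        name: fixed.get(name, S0_u[name] * df0 / (df0 + 2.0)) for name in terms
    }
    sig2_beta = fixed.get("beta", S0_beta * df0 / (df0 + 2.0)) if has_brr else 0.0
    sig2_e = fixed.get("resid", (1.0 - mcmc.prior_R2) * var_y)
    e = y_cur - mu

    acc_eta = np.zeros(n)
    acc_u = {name: np.zeros(n) for name in terms}
    acc_beta = np.zeros(q) if has_brr else None
    acc_var: dict[str, float] = {name: 0.0 for name in terms}
    acc_var["resid"] = 0.0
    if has_brr:
        acc_var["beta"] = 0.0
    acc_mu = 0.0
    sig2_e_trace: list[float] = []
    kept = 0

    n_mis = int((~obs).sum())
    for it in range(mcmc.n_iter):
        # intercept (flat prior)
        r = e + mu
        mu = float(rng.normal(r.mean(), np.sqrt(sig2_e / n)))
        e = r - mu

        # kernel blocks on eigenvector coordinates
        for name in terms:
            P, dk = Phi[name], d_eig[name]
            if len(dk):
                r_k = e + P @ delta[name]
                prec = dk / sig2_e + 1.0 / sig2_u[name]
                mean = (P.T @ r_k) / sig2_e / prec
                delta[name] = mean + rng.standard_normal(len(dk)) / np.sqrt(prec)
                e = r_k - P @ delta[name]
            if name not in fixed:
                ss = float(delta[name] @ delta[name])
                sig2_u[name] = (ss + df0 * S0_u[name]) / rng.chisquare(df0 + len(dk))

        # Bayesian ridge block, sampled jointly
        if has_brr:
            r_b = e + X @ beta
            C = XtX / sig2_e + np.eye(q) / sig2_beta
            cf = cho_factor(C, lower=True)
            mean = cho_solve(cf, X.T @ r_b / sig2_e)
            z = rng.standard_normal(q)
            beta = mean + solve_triangular(cf[0].T, z, lower=False)
            e = r_b - X @ beta
            if "beta" not in fixed:
                sig2_beta = (float(beta @ beta) + df0 * S0_beta) / rng.chisquare(df0 + q)

        if "resid" not in fixed:
            sig2_e = (float(e @ e) + df0 * S0_e) / rng.chisquare(df0 + n)

        # data augmentation for missing responses
        if n_mis:
            eta_mis = y_cur[~obs] - e[~obs]
            draw = eta_mis + rng.standard_normal(n_mis) * np.sqrt(sig2_e)
            y_cur[~obs] = draw
            e[~obs] = draw - eta_mis

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            kept += 1
            acc_eta += y_cur - e
            acc_mu += mu
            for name in terms:
                acc_u[name] += Phi[name] @ delta[name]
                acc_var[name] += sig2_u[name]
            acc_var["resid"] += sig2_e
            if has_brr:
                acc_beta += beta
                acc_var["beta"] += sig2_beta
            sig2_e_trace.append(sig2_e)

    var_components = {k: v / kept for k, v in acc_var.items()}
    effects = {name: acc_u[name] / kept for name in terms}
    if has_brr:
        effects["beta"] = acc_beta / kept
    rhat = _split_rhat(np.asarray(sig2_e_trace))
    if np.isfinite(rhat) and rhat > 1.1:
        warnings.warn(f"residual-variance chain may not have converged (R-hat {rhat:.3f})")

    return FitResult(
        mu_hat=acc_mu / kept,
        var_components=var_components,
        effects=effects,
        y_hat=acc_eta / kept,
        samples_kept=kept,
        obs_keys=list(labels),
        predictor=spec.predictor,
        strategy=spec.strategy,
        n_missing=n_mis,
        y_obs_mean=float(np.mean(y[obs])),
        diagnostics={"rhat_resid": rhat},
    )


def predict_missing(fit_result: FitResult, obs_keys: list) -> np.ndarray:
    """Posterior-mean predictions for the requested observation keys."""
    index = {key: i for i, key in enumerate(fit_result.obs_keys)}
    unknown = [k for k in obs_keys if k not in index]
    if unknown:
        raise ValidationError(f"unknown observation key: {unknown[0]}")
    return fit_result.y_hat[[index[k] for k in obs_keys]]


def heritability(
    var_geno: float, var_ge: float, var_resid: float, n_env_mean: float
) -> float:
    """Line-mean heritability h2 = s_g^2 / (s_g^2 + s_gE^2/nE + s^2/nE)."""
    denom = var_geno + var_ge / n_env_mean + var_resid / n_env_mean
    if denom == 0:
        return float("nan")
    return var_geno / denom


def variance_report(fits: dict[str, FitResult], n_env_mean: float) -> pd.DataFrame:
    """Variance-component table from full-data E+G+GE fits, one per trait.

    Rows mirror the (component, VarComp, trait, heritability, CV, n_Env)
    layout with components Env:Line / Line / Env / Residual.  Heritability
    is on a line-mean basis and CV = sd(residual) / mean(y).
    """
    rows = []
    for trait, fr in fits.items():
        if fr.predictor != "E+G+GE" or fr.strategy != "NoEC":
            raise ValidationError("variance report requires E+G+GE fits under NoEC")
        if fr.n_missing:
            raise ValidationError("variance report requires complete data (no missing)")
        vc = fr.var_components
        h2 = heritability(vc["g"], vc.get("gE", 0.0), vc["resid"], n_env_mean)
        cv = float(np.sqrt(vc["resid"]) / fr.y_obs_mean) if fr.y_obs_mean else float("nan")
        for comp, key in (
            ("Env:Line", "gE"),
            ("Line", "g"),
            ("Env", "E"),
            ("Residual", "resid"),
        ):
            rows.append(
                {
                    "Component": comp,
                    "VarComp": vc.get(key, 0.0),
                    "Trait": trait,
                    "Heritability": h2,
                    "CV": cv,
                    "n_Env": n_env_mean,
                }
            )
    return pd.DataFrame(rows)
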