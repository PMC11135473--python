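"""Synthetic multi-environment trial generator.

Emulates the structure of real genomic-prediction datasets — a few to a
couple of dozen environments, tens to hundreds of genotypes, SNP dosages
coded 0/1/2 and per-environment covariates — under the additive
genotype + environment + interaction model

    y_ij = mu + E_i + g_j + (gE)_ij + eps_ij.

Markers are Binomial(2, f) with per-marker allele frequencies drawn from
U(0.1, 0.5); genetic values are g = M_std alpha with alpha ~ N(0, var_geno/p)
so the realized genetic variance is close to its target.  Covariates are
i.i.d. standard normal per environment.  The environmental main effect is
driven, per ``env_signal``, by

* ``linear``  — a random linear combination of the first
  ``n_informative_cov`` covariates,
* ``product`` — the product of the first two informative covariates (a
  signal that pairwise feature engineering can linearize but raw-covariate
  selection cannot), or
* ``none``    — pure noise, independent of every covariate,

standardized and mixed with a small independent noise component
(signal fraction 0.9) and rescaled to variance ``var_env``.  A configurable
fraction of (environment, genotype) cells is dropped to produce unbalanced
designs.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io_data import EnvCovariateTable, MarkerMatrix, PhenotypeTable, ValidationError

__all__ = ["SimConfig", "simulate"]

SIGNAL_FRACTION = 0.9  # share of env-effect variance carried by the covariate signal


@dataclass
class SimConfig:
    """Sizes, variance targets and the environment-signal scenario."""

    n_geno: int = 100
    n_env: int = 5
    n_markers: int = 1000
    n_cov: int = 20
    var_env: float = 1.0
    var_geno: float = 1.0
    var_ge: float = 0.5
    var_resid: float = 1.0
    env_signal: str = "linear"
    n_informative_cov: int = 2
    missing_fraction: float = 0.0
    mu: float = 10.0
    seed: int = 0
    trait: str = "Y"

    def __post_init__(self) -> None:
        if self.env_signal not in ("linear", "product", "none"):
            raise ValidationError(f"unknown env_signal {self.env_signal!r}")
        if self.n_informative_cov > self.n_cov:
            raise ValidationError("n_informative_cov cannot exceed n_cov")
        if self.env_signal == "product" and self.n_informative_cov < 2:
            raise ValidationError("product signal needs >= 2 informative covariates")
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError("missing_fraction must be in [0, 1)")
        if self.n_env < 2 or self.n_geno < 2 or self.n_markers < 1 or self.n_cov < 1:
            raise ValidationError("sizes too small to simulate a trial")
        variances = (self.var_env, self.var_geno, self.var_ge, self.var_resid)
        if any(v < 0 for v in variances) or not any(v > 0 for v in variances):
            raise ValidationError("variances must be >= 0 with at least one positive")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def simulate(cfg: SimConfig):
    """Generate (PhenotypeTable, MarkerMatrix, EnvCovariateTable, truth)."""
    rng = np.random.default_rng(cfg.seed)
    env_ids = [f"E{i+1:02d}" for i in range(cfg.n_env)]
    geno_ids = [f"G{j+1:04d}" for j in range(cfg.n_geno)]
    marker_ids = [f"m{m+1:05d}" for m in range(cfg.n_markers)]
    cov_ids = [f"cov{k+1:03d}" for k in range(cfg.n_cov)]

    freqs = rng.uniform(0.1, 0.5, size=cfg.n_markers)
    dosages = rng.binomial(2, freqs, size=(cfg.n_geno, cfg.n_markers))
    markers = MarkerMatrix(geno_ids, marker_ids, dosages)

    X = dosages.astype(float)
    sd = X.std(axis=0, ddof=1)
    poly = sd > 0
    M = np.zeros_like(X)
    M[:, poly] = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
    alpha = rng.normal(0.0, np.sqrt(cfg.var_geno / cfg.n_markers), size=cfg.n_markers)
    g = M @ alpha

    covs = rng.normal(size=(cfg.n_env, cfg.n_cov))
    cov_table = EnvCovariateTable(pd.DataFrame(covs, index=env_ids, columns=cov_ids))

    informative = cov_ids[: cfg.n_informative_cov]
    if cfg.env_signal == "linear":
        weights = rng.normal(size=cfg.n_informative_cov)
        signal = covs[:, : cfg.n_informative_cov] @ weights
    elif cfg.env_signal == "product":
        signal = covs[:, 0] * covs[:, 1]
    else:
        signal = np.zeros(cfg.n_env)
    noise = rng.normal(size=cfg.n_env)
    if cfg.env_signal == "none":
        E_raw = noise
    else:
        E_raw = (
            np.sqrt(SIGNAL_FRACTION) * _standardize(signal)
            + np.sqrt(1.0 - SIGNAL_FRACTION) * _standardize(noise)
        )
    # final standardization pins the realized environment variance exactly
    E = np.sqrt(cfg.var_env) * _standardize(E_raw)

    ge = rng.normal(0.0, np.sqrt(cfg.var_ge), size=(cfg.n_env, cfg.n_geno))
    eps = rng.normal(0.0, np.sqrt(cfg.var_resid), size=(cfg.n_env, cfg.n_geno))
    y = cfg.mu + E[:, None] + g[None, :] + ge + eps

    records = []
    for i, env in enumerate(env_ids):
        for j, geno in enumerate(geno_ids):
            records.append((env, geno, cfg.trait, y[i, j]))
    df = pd.DataFrame(records, columns=["env", "geno", "trait", "value"])
    n_drop = int(np.floor(cfg.missing_fraction * len(df)))
    if n_drop:
        drop_idx = rng.choice(len(df), size=n_drop, replace=False)
        df = df.drop(index=drop_idx).reset_index(drop=True)
        # dropping whole cells can silently empty an environment; forbid that
        if df["env"].nunique() < 2:
            raise ValidationError("missing_fraction left fewer than 2 environments")
    phen = PhenotypeTable(df)

    truth = {
        "config": asdict(cfg),
        "alpha": alpha.tolist(),
        "g": g.tolist(),
        "E": dict(zip(env_ids, E.tolist())),
        "informative_covariates": informative,
        "variance_targets": {
            "E": cfg.var_env,
            "g": cfg.var_geno,
            "gE": cfg.var_ge,
            "resid": cfg.var_resid,
        },
    }
    return phen, markers, cov_table, truth
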