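"""Kernel construction for the multi-environment GBLUP models.

The genomic relationship matrix follows VanRaden's linear kernel on
centred, standardized dosages, G = M M' / p.  Observation-level kernels
are expansions through incidence matrices:

* genotype kernel           Kg     = Zg G Zg'
* environment kernel, NoEC  KE     = XE XE' / I
* environment kernel, EC/FE KE^W   = XE (W W' / q) XE' / I
* interaction kernel        KGE    = Kg ∘ KE   (Hadamard; PSD by the Schur
  product theorem)

where Zg and XE are 0/1 incidence matrices of genotype and environment
membership and W is the I x q matrix of selected, standardized covariates.
The I x I covariate kernel W W' is divided by the number of selected
covariates q (mirroring the /p in G) and the expansion by the number of
environments I.

All constructors validate symmetry and positive semidefiniteness;
eigenvalues in a small negative numerical band are clipped to zero, larger
negatives raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_data import EnvCovariateTable, MarkerMatrix, PhenotypeTable, ValidationError

__all__ = [
    "KernelMatrix",
    "DesignMatrices",
    "genomic_relationship",
    "build_designs",
    "env_kernel_noec",
    "env_kernel_from_covariates",
    "ge_kernel",
    "genotype_kernel",
]

PSD_TOL = 1e-8
SYM_TOL = 1e-10


@dataclass
class KernelMatrix:
    """Labelled symmetric positive-semidefinite matrix."""

    labels: list
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if V.shape != (n, n):
            raise ValidationError(f"kernel shape {V.shape} does not match {n} labels")
        scale = max(1.0, float(np.max(np.abs(V))))
        if np.max(np.abs(V - V.T)) > SYM_TOL * scale:
            raise ValidationError("kernel is not symmetric")
        V = (V + V.T) / 2.0
        w = np.linalg.eigvalsh(V)
        lam_max = max(w[-1], 0.0)
        if w[0] < -PSD_TOL * max(lam_max, 1.0):
            raise ValidationError(
                f"kernel is not positive semidefinite (min eig {w[0]:.3e})"
            )
        self.values = V

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        idx = [str(label) for label in self.labels]
        return pd.DataFrame(self.values, index=idx, columns=idx)


@dataclass
class DesignMatrices:
    """Observation-level incidence matrices for one trait.

    Rows are ordered canonically by (environment, genotype) and include
    rows whose response is missing — those are the prediction targets.
    """

    Z_g: np.ndarray
    X_E: np.ndarray
    obs_keys: list[tuple[str, str]]
    geno_ids: list[str]
    env_ids: list[str]
    y: np.ndarray  # response per observation, NaN for missing

    @property
    def n_obs(self) -> int:
        return len(self.obs_keys)

    @property
    def n_env(self) -> int:
        return len(self.env_ids)


def genomic_relationship(markers: MarkerMatrix) -> KernelMatrix:
    """VanRaden genomic relationship G = M M' / p on standardized dosages.

    Each marker column is centred to mean zero and divided by its sample
    standard deviation (denominator J-1).  Monomorphic columns cannot be
    standardized; they are dropped with a warning and p adjusted.
    """
    X = markers.values.astype(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all marker columns are constant; no genomic information")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} monomorphic marker(s) before standardization"
        )
    X = X[:, keep]
    M = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    p = M.shape[1]
    G = M @ M.T / p
    return KernelMatrix(list(markers.geno_ids), G, "G")


def build_designs(
    phen: PhenotypeTable,
    trait: str,
    markers: MarkerMatrix,
    covs: EnvCovariateTable,
) -> DesignMatrices:
    """Incidence matrices Zg (n x J) and XE (n x I) for one trait.

    Environments are those with records for the trait (sorted); genotypes
    are the marker panel's genotypes in their given order.  Every phenotype
    record must reference a known genotype and environment.
    """
    df = phen.for_trait(trait)
    if df.empty:
        raise ValidationError(f"no records for trait {trait!r}")
    unknown_g = sorted(set(df["geno"]) - set(markers.geno_ids))
    if unknown_g:
        raise ValidationError(f"unknown genotype {unknown_g[0]}")
    unknown_e = sorted(set(df["env"]) - set(covs.env_ids))
    if unknown_e:
        raise ValidationError(f"unknown environment {unknown_e[0]}")
    env_ids = sorted(df["env"].unique())
    geno_ids = list(markers.geno_ids)
    df = df.sort_values(["env", "geno"], kind="mergesort").reset_index(drop=True)
    g_index = {g: j for j, g in enumerate(geno_ids)}
    e_index = {e: i for i, e in enumerate(env_ids)}
    n = len(df)
    Z_g = np.zeros((n, len(geno_ids)))
    X_E = np.zeros((n, len(env_ids)))
    for row, (e, g) in enumerate(zip(df["env"], df["geno"])):
        Z_g[row, g_index[g]] = 1.0
        X_E[row, e_index[e]] = 1.0
    obs_keys = list(zip(df["env"], df["geno"]))
    return DesignMatrices(Z_g, X_E, obs_keys, geno_ids, env_ids, df["value"].to_numpy(float))


def env_kernel_noec(d: DesignMatrices) -> KernelMatrix:
    """Identity-based environment kernel KE = XE XE' / I.

    Entry 1/I when two observations share an environment, 0 otherwise.
    """
    I = d.n_env
    if I < 2:
        raise ValidationError("need at least 2 environments")
    K = d.X_E @ d.X_E.T / I
    return KernelMatrix(list(d.obs_keys), K, "KE_noec")


def env_kernel_from_covariates(
    Wsel: np.ndarray, d: DesignMatrices, kind: str = "KE_ec"
) -> KernelMatrix:
    """Covariate-based environment kernel, expanded to observation level.

    ``Wsel`` is the I x q matrix of selected standardized covariates in the
    order of ``d.env_ids``.  K_EC = W W'/q (I x I) and the expanded kernel
    is XE K_EC XE' / I.
    """
    Wsel = np.asarray(Wsel, dtype=float)
    if Wsel.ndim != 2 or Wsel.shape[0] != d.n_env:
        raise ValidationError("covariate matrix rows must match environments")
    q = Wsel.shape[1]
    if q == 0:
        raise ValidationError(
            "no selected covariates; fall back to the identity environment kernel"
        )
    K_EC = Wsel @ Wsel.T / q
    K = d.X_E @ K_EC @ d.X_E.T / d.n_env
    return KernelMatrix(list(d.obs_keys), K, kind)


def ge_kernel(kg: KernelMatrix, ke: KernelMatrix) -> KernelMatrix:
    """Genotype-by-environment kernel: Hadamard product Kg ∘ KE."""
    if kg.labels != ke.labels:
        raise ValidationError("kernel observation labels do not match")
    return KernelMatrix(list(kg.labels), kg.values * ke.values, "KGE")


def genotype_kernel(g: KernelMatrix, d: DesignMatrices) -> KernelMatrix:
    """Expand the J x J genomic relationship to observations: Kg = Zg G Zg'."""
    if g.n != d.Z_g.shape[1]:
        raise ValidationError(
            f"G dimension {g.n} does not match {d.Z_g.shape[1]} genotype columns"
        )
    K = d.Z_g @ g.values @ d.Z_g.T
    return KernelMatrix(list(d.obs_keys), K, "Kg")
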