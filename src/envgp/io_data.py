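"""Reading, validation and writing of the three input tables.

All downstream modules consume only the validated containers defined here:

* :class:`PhenotypeTable` — long-format trait observations by environment x
  genotype.  Missing values are retained as records (they mark prediction
  targets) but are never used in training likelihoods or selection
  correlations.
* :class:`MarkerMatrix` — genotypes x markers allele dosages coded 0/1/2.
* :class:`EnvCovariateTable` — environments x covariates, each column tagged
  with a provenance string so engineered columns can be told apart from
  measured ones.

CSV dialect is fixed: comma separated, UTF-8, header row mandatory, ``.``
decimal.  Environment ids are sorted into canonical order on load so that
every kernel built from the same inputs is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "PhenotypeTable",
    "MarkerMatrix",
    "EnvCovariateTable",
    "read_phenotypes",
    "read_markers",
    "read_env_covariates",
    "write_results",
]

#: placeholder printed in MSE columns of "Across" summary rows
ACROSS_DASH = "–"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class PhenotypeTable:
    """Long-format phenotype records ``(env, geno, trait, value)``.

    ``value`` is float with NaN marking a missing response.  The
    ``(env, geno, trait)`` triple is unique and at least two distinct
    environments are present (leave-one-environment-out needs >= 2).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["env", "geno", "trait", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns {missing}")
        df = self.data[required].copy()
        df["env"] = df["env"].astype(str)
        df["geno"] = df["geno"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        dup = df.duplicated(subset=["env", "geno", "trait"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["env", "geno", "trait"]].tolist()
            raise ValidationError(f"duplicate (env, geno, trait) record: {tuple(key)}")
        n_env = df["env"].nunique()
        if n_env < 2:
            raise ValidationError("at least 2 environments required")
        if np.isinf(df["value"].to_numpy(dtype=float)).any():
            raise ValidationError("phenotype values must be finite or missing")
        df = df.sort_values(["trait", "env", "geno"], kind="mergesort").reset_index(drop=True)
        self.data = df

    @property
    def env_ids(self) -> list[str]:
        return sorted(self.data["env"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.data[self.data["trait"] == trait].reset_index(drop=True)

    def mask_env(self, trait: str, env: str) -> "PhenotypeTable":
        """Return a copy with responses of ``env`` set to missing for ``trait``."""
        df = self.data.copy()
        sel = (df["trait"] == trait) & (df["env"] == env)
        df.loc[sel, "value"] = np.nan
        return PhenotypeTable(df)


@dataclass
class MarkerMatrix:
    """Genotype x marker dosage matrix with entries in {0, 1, 2}."""

    geno_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.geno_ids = [str(g) for g in self.geno_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValidationError("marker matrix must be 2-dimensional")
        if len(set(self.geno_ids)) != len(self.geno_ids):
            raise ValidationError("genotype ids must be unique")
        if values.shape != (len(self.geno_ids), len(self.marker_ids)):
            raise ValidationError("marker matrix shape does not match id lists")
        if values.shape[0] < 2 or values.shape[1] < 1:
            raise ValidationError("need at least 2 genotypes and 1 marker")
        if not np.isin(values, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(values, (0, 1, 2)))[0]
            raise ValidationError(
                f"dosage outside {{0,1,2}} at ({self.geno_ids[bad[0]]}, "
                f"{self.marker_ids[bad[1]]})"
            )
        self.values = values.astype(np.int8)

    @property
    def n_genotypes(self) -> int:
        return len(self.geno_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class EnvCovariateTable:
    """Environment x covariate table with per-column provenance labels.

    Provenance is ``original`` for measured covariates, or machine-parseable
    strings like ``pairwise:div:tmax:rain`` / ``unary:boxcox0.25:srad`` for
    engineered ones.  ``skip_log`` records transforms that were skipped by
    the feature-engineering guards (division by ~0, log of non-positives).
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    skip_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate environment id: {dup}")
        if len(df.index) < 2:
            raise ValidationError("at least 2 environments required")
        if df.columns.duplicated().any():
            raise ValidationError("covariate column names must be unique")
        vals = df.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite covariate value at ({df.index[i]}, {df.columns[j]})"
            )
        df = df.sort_index().astype(float)
        self.data = df
        if not self.provenance:
            self.provenance = {c: "original" for c in df.columns}
        else:
            missing = [c for c in df.columns if c not in self.provenance]
            if missing:
                raise ValidationError(f"columns without provenance: {missing}")

    @property
    def env_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_environments(self) -> int:
        return len(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def subset_envs(self, envs: list[str]) -> "EnvCovariateTable":
        missing = [e for e in envs if e not in self.data.index]
        if missing:
            raise ValidationError(f"unknown environment ids: {missing}")
        return EnvCovariateTable(
            self.data.loc[sorted(envs)],
            provenance=dict(self.provenance),
        )


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV with columns ``env, geno, trait, value``.

    Non-numeric or blank values become missing records (they stay in the
    table as prediction targets).
    """
    df = pd.read_csv(path, dtype={"env": str, "geno": str, "trait": str})
    return PhenotypeTable(df)


def read_markers(path) -> MarkerMatrix:
    """Read a marker CSV: first column genotype id, then integer dosages."""
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    # blank cells arrive as NaN after pandas parsing
    try:
        numeric = vals.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric dosage entry: {exc}") from None
    if np.isnan(numeric).any():
        i, j = np.argwhere(np.isnan(numeric))[0]
        raise ValidationError(
            f"missing dosage at ({df.index[i]}, {df.columns[j]}); impute upstream"
        )
    return MarkerMatrix(list(df.index), list(df.columns), numeric)


def read_env_covariates(path) -> EnvCovariateTable:
    """Read an environment-covariate CSV: first column env id, rest numeric."""
    df = pd.read_csv(path, index_col=0)
    return EnvCovariateTable(df)


def write_results(result, path) -> None:
    """Write a cross-validation result as a report CSV.

    One row per (predictor, trait, env) plus an "Across" row per
    (predictor, trait).  Relative efficiencies are rounded to 3 decimals in
    the report; full precision is retained in a companion ``*.full.csv``.
    Across rows carry an en dash in the MSE columns.
    """
    path = str(path)
    report = result.to_frame()
    full_path = path[:-4] + ".full.csv" if path.endswith(".csv") else path + ".full.csv"
    report.to_csv(full_path, index=False)

    pretty = report.copy()
    for col in pretty.columns:
        if col.startswith("re_"):
            pretty[col] = pretty[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.3f}"
            )
        if col.startswith("mse_"):
            pretty[col] = [
                ACROSS_DASH if env == "Across" else ("" if pd.isna(v) else repr(float(v)))
                for env, v in zip(pretty["env"], pretty[col])
            ]
    pretty.to_csv(path, index=False)
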