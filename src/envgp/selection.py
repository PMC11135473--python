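"""Correlation-based covariate selection with a threshold cascade.

For one cross-validation fold (one held-out environment), each candidate
covariate is scored by the Pearson correlation between the training-set
responses and the covariate value of each observation's environment.  The
held-out environment's responses never enter the correlations, so selection
is leak-free by construction.

Selection walks a strictly decreasing threshold cascade (default
0.5 -> 0.4 -> 0.3): the first threshold at which at least one covariate
reaches ``|r| >= threshold`` wins and fixes the selected set.  If no
covariate qualifies even at the last threshold the fold degrades to the
identity-based environmental kernel (no covariates).

Selected columns are centre/scaled with statistics over *all* environments:
covariates, unlike responses, are known for the held-out environment and
its kernel row must be built from them — this uses no response information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_data import EnvCovariateTable, PhenotypeTable, ValidationError

__all__ = ["SelectionResult", "env_correlation", "select", "scale_selected"]

DEFAULT_THRESHOLDS = (0.5, 0.4, 0.3)


@dataclass
class SelectionResult:
    """Outcome of the per-fold threshold cascade.

    ``threshold_used`` is None when no covariate qualified (the fold falls
    back to training without covariates).  ``correlations`` maps every
    scoreable column to its observation-level Pearson r; columns whose
    correlation is undefined (constant over training) are absent.
    """

    selected_columns: list[str]
    threshold_used: float | None
    correlations: dict[str, float]
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.selected_columns

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_columns": self.selected_columns,
                "threshold_used": self.threshold_used,
                "correlations": self.correlations,
                "scaling": {k: list(v) for k, v in self.scaling.items()},
            },
            indent=2,
        )


def env_correlation(
    column: np.ndarray,
    env_ids: list[str],
    phen: PhenotypeTable,
    trait: str,
    train_envs: set[str],
) -> float:
    """Observation-level Pearson correlation of a covariate with a trait.

    Each non-missing training observation contributes the pair
    ``(covariate value of its environment, response)``.  Returns NaN when
    the correlation is undefined: fewer than 3 usable observations or a
    covariate that is constant across the training environments.
    """
    env_to_val = dict(zip(env_ids, np.asarray(column, dtype=float)))
    df = phen.for_trait(trait)
    use = df["env"].isin(train_envs) & df["value"].notna()
    if use.sum() < 3:
        return float("nan")
    x = df.loc[use, "env"].map(env_to_val).to_numpy(dtype=float)
    y = df.loc[use, "value"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def select(
    W: EnvCovariateTable,
    phen: PhenotypeTable,
    trait: str,
    test_env: str,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> SelectionResult:
    """Run the threshold cascade for one leave-one-environment-out fold."""
    if test_env not in W.env_ids:
        raise ValidationError(f"test environment {test_env!r} not in covariate table")
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValidationError("thresholds must be strictly decreasing")
    train_envs = set(W.env_ids) - {test_env}
    correlations: dict[str, float] = {}
    df = phen.for_trait(trait)
    use = df["env"].isin(train_envs) & df["value"].notna()
    if use.sum() >= 3:
        env_pos = {e: i for i, e in enumerate(W.env_ids)}
        rows = df.loc[use, "env"].map(env_pos).to_numpy()
        X = W.data.to_numpy(dtype=float)[rows]  # n_obs x q covariate expansion
        y = df.loc[use, "value"].to_numpy(dtype=float)
        y_c = y - y.mean()
        sy = np.sqrt((y_c**2).sum())
        Xc = X - X.mean(axis=0)
        sx = np.sqrt((Xc**2).sum(axis=0))
        if sy > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                r_all = (Xc.T @ y_c) / (sx * sy)
            for col, r in zip(W.columns, r_all):
                if np.isfinite(r):
                    correlations[col] = float(r)
    for thr in thresholds:
        chosen = [c for c in W.columns if c in correlations and abs(correlations[c]) >= thr]
        if chosen:
            return SelectionResult(chosen, thr, correlations)
    return SelectionResult([], None, correlations)


def scale_selected(W: EnvCovariateTable, sel: SelectionResult) -> np.ndarray:
    """Standardize the selected columns over all I environments.

    Uses the sample mean and sample standard deviation (denominator I-1) of
    each column over the full environment set.  Zero-variance columns are
    dropped with a warning (and removed from ``sel.selected_columns``).
    Records the (mean, sd) pairs in ``sel.scaling``.
    """
    if sel.is_empty:
        raise ValidationError("no columns selected; nothing to scale")
    kept = []
    out = []
    for col in sel.selected_columns:
        x = W.data[col].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0:
            warnings.warn(f"covariate {col!r} has zero variance; dropped from selection")
            continue
        kept.append(col)
        sel.scaling[col] = (mu, sd)
        out.append((x - mu) / sd)
    sel.selected_columns = kept
    if not out:
        sel.threshold_used = None
        return np.empty((W.n_environments, 0))
    return np.column_stack(out)
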