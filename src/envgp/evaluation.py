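"""Leave-one-environment-out cross-validation and relative efficiencies.

Each environment serves once as an entirely held-out test set; the model is
trained on all remaining environments and predicts every test observation.
Performance is the mean squared error (MSE) on the test environment, and
strategies are compared through relative efficiencies

    RE_NoEC_vs_EC = MSE(NoEC) / MSE(EC)
    RE_NoEC_vs_FE = MSE(NoEC) / MSE(FE)
    RE_EC_vs_FE   = MSE(EC)   / MSE(FE)

so RE > 1 means the denominator strategy predicted better.  "Across" rows
aggregate the per-environment REs of one (predictor, trait) by their
arithmetic mean.

Per fold and strategy the pipeline is: engineer covariates (FE only) ->
correlation-based selection excluding the test environment -> kernel
construction -> Gibbs fit with the test responses masked -> prediction ->
MSE.  Folds whose selection comes back empty reuse the identity-based
environment kernel (logged), so EC/FE degrade gracefully to NoEC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes import MCMCConfig, ModelSpec, FitResult, fit
from .feature_engineering import FEConfig, engineer
from .io_data import EnvCovariateTable, MarkerMatrix, PhenotypeTable, ValidationError
from .kernels import (
    build_designs,
    env_kernel_from_covariates,
    env_kernel_noec,
    ge_kernel,
    genomic_relationship,
    genotype_kernel,
)
from .selection import DEFAULT_THRESHOLDS, scale_selected, select

__all__ = [
    "CVResult",
    "loeo_folds",
    "mse",
    "relative_efficiency",
    "across_summary",
    "run_cv",
    "summary_table",
]

logger = logging.getLogger("envgp")

STRATEGY_MSE_COL = {"NoEC": "mse_noec", "EC": "mse_ec", "FE": "mse_fe"}
RE_COLS = {
    "re_noec_vs_ec": ("NoEC", "EC"),
    "re_ec_vs_fe": ("EC", "FE"),
    "re_noec_vs_fe": ("NoEC", "FE"),
}


@dataclass
class CVResult:
    """Per-fold MSEs and relative efficiencies, with Across summaries.

    ``rows`` has one record per (predictor, trait, env); ``across_rows``
    one per (predictor, trait) with the arithmetic-mean REs.  ``details``
    (optional) maps (predictor, trait, env, strategy) to the fold's
    selection result, predictions and observed values, for audit trails
    and leak-freedom checks.
    """

    rows: pd.DataFrame
    across_rows: pd.DataFrame
    details: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Report layout: env rows followed by the Across row per group."""
        across = self.across_rows.copy()
        across["env"] = "Across"
        out = pd.concat([self.rows, across], ignore_index=True)
        out["_is_across"] = (out["env"] == "Across").astype(int)
        out = out.sort_values(
            ["predictor", "trait", "_is_across", "env"], kind="mergesort"
        ).drop(columns="_is_across")
        return out.reset_index(drop=True)


def loeo_folds(phen: PhenotypeTable, trait: str) -> list[tuple[str, list[str]]]:
    """One fold per environment with data for the trait.

    Environments with zero non-missing observations are excluded with a
    warning (they cannot be scored).
    """
    df = phen.for_trait(trait)
    envs = sorted(df["env"].unique())
    usable = [e for e in envs if df.loc[df["env"] == e, "value"].notna().any()]
    dropped = sorted(set(envs) - set(usable))
    if dropped:
        warnings.warn(f"environments without observations for {trait!r} excluded: {dropped}")
    if len(usable) < 2:
        raise ValidationError(f"trait {trait!r} needs >= 2 environments with data")
    return [(e, [t for t in usable if t != e]) for e in usable]


def mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared deviation between observed and predicted values."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size == 0:
        raise ValidationError("observed and predicted must be equal-length, non-empty")
    return float(np.mean((observed - predicted) ** 2))


def relative_efficiency(mse_a: float, mse_b: float) -> float:
    """RE = MSE(a) / MSE(b); RE > 1 means strategy b predicted better."""
    if mse_b <= 0:
        raise ValidationError("denominator MSE must be positive")
    return mse_a / mse_b


def across_summary(per_env_res: "np.ndarray | list[float]") -> float:
    """Across-environment aggregation: arithmetic mean of per-env REs."""
    arr = np.asarray(per_env_res, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("need at least one finite relative efficiency")
    return float(arr.mean())


def _strategy_inputs(
    strategy: str,
    W: EnvCovariateTable,
    phen: PhenotypeTable,
    trait: str,
    test_env: str,
    d,
    ke_noec,
    fe_cfg: FEConfig,
    thresholds,
):
    """Environment kernel, covariate block and selection for one strategy."""
    if strategy == "NoEC":
        return ke_noec, None, None, "noec"
    table = engineer(W, fe_cfg) if strategy == "FE" else W
    sel = select(table, phen, trait, test_env, thresholds)
    if sel.is_empty:
        logger.info(
            "fold trait=%s env=%s strategy=%s: empty selection, fallback to NoEC",
            trait, test_env, strategy,
        )
        return ke_noec, None, sel, "noec"
    Wsel = scale_selected(table, sel)
    if Wsel.shape[1] == 0:  # all selected columns were degenerate
        return ke_noec, None, sel, "noec"
    kind = "KE_fe" if strategy == "FE" else "KE_ec"
    ke = env_kernel_from_covariates(Wsel, d, kind)
    brr_X = d.X_E @ Wsel
    return ke, brr_X, sel, strategy


def run_cv(
    phen: PhenotypeTable,
    markers: MarkerMatrix,
    covs: EnvCovariateTable,
    predictors: tuple[str, ...] = ("E+G",),
    strategies: tuple[str, ...] = ("NoEC", "EC", "FE"),
    traits: tuple[str, ...] | None = None,
    fe_cfg: FEConfig | None = None,
    mcmc: MCMCConfig | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    collect_details: bool = False,
) -> CVResult:
    """Full leave-one-environment-out evaluation.

    For every (predictor, trait, fold, strategy) the test environment's
    responses are masked, kernels are built per strategy, the Gibbs model
    is fitted and the held-out observations predicted.  Per-fold chains use
    seed ``mcmc.seed + fold_index``.  Identical model structures within a
    fold (e.g. a BRR predictor whose selection is empty) share one fit.
    """
    fe_cfg = fe_cfg or FEConfig()
    mcmc = mcmc or MCMCConfig()
    traits = tuple(traits) if traits else tuple(phen.traits)
    G = genomic_relationship(markers)

    records: list[dict] = []
    details: dict = {}
    for trait in traits:
        folds = loeo_folds(phen, trait)
        for fold_idx, (test_env, _train) in enumerate(folds):
            phen_m = phen.mask_env(trait, test_env)
            d = build_designs(phen_m, trait, markers, covs)
            W = covs.subset_envs(d.env_ids)
            kg = genotype_kernel(G, d)
            ke_noec = env_kernel_noec(d)
            mcmc_fold = replace(mcmc, seed=mcmc.seed + fold_idx)

            # observed (unmasked) test responses, aligned with design rows
            full = build_designs(phen, trait, markers, covs)
            assert full.obs_keys == d.obs_keys
            test_mask = np.array(
                [k[0] == test_env and np.isfinite(v) for k, v in zip(full.obs_keys, full.y)]
            )

            strat_inputs = {}
            for strategy in strategies:
                try:
                    strat_inputs[strategy] = _strategy_inputs(
                        strategy, W, phen_m, trait, test_env, d, ke_noec, fe_cfg, thresholds
                    )
                except ValidationError as exc:
                    raise ValidationError(
                        f"fold failed (trait={trait}, env={test_env}, "
                        f"strategy={strategy}): {exc}"
                    ) from exc

            fit_cache: dict[tuple, FitResult] = {}
            for predictor in predictors:
                include_ge = "GE" in predictor
                for strategy in strategies:
                    ke, brr_X, sel, kernel_source = strat_inputs[strategy]
                    use_brr = "BRR" in predictor and brr_X is not None
                    key = (kernel_source, include_ge, use_brr)
                    if key not in fit_cache:
                        kern = {"E": ke, "g": kg}
                        if include_ge:
                            kern["gE"] = ge_kernel(kg, ke)
                        spec = ModelSpec(
                            predictor=predictor,
                            strategy=strategy,
                            kernels=kern,
                            brr_covariates=brr_X if use_brr else None,
                        )
                        try:
                            fit_cache[key] = fit(spec, d.y, mcmc_fold)
                        except ValidationError as exc:
                            raise ValidationError(
                                f"fold failed (predictor={predictor}, trait={trait}, "
                                f"env={test_env}, strategy={strategy}): {exc}"
                            ) from exc
                    fr = fit_cache[key]
                    pred = fr.y_hat[test_mask]
                    obs_vals = full.y[test_mask]
                    fold_mse = mse(obs_vals, pred)
                    if test_mask.sum() < 3:
                        warnings.warn(
                            f"test environment {test_env} has <3 observations; "
                            "MSE is reported but noisy"
                        )
                    records.append(
                        {
                            "predictor": predictor,
                            "trait": trait,
                            "env": test_env,
                            "strategy": strategy,
                            "mse": fold_mse,
                            "threshold_used": None if sel is None else sel.threshold_used,
                            "n_selected": None if sel is None else len(sel.selected_columns),
                        }
                    )
                    logger.info(
                        "predictor=%s trait=%s env=%s strategy=%s threshold=%s "
                        "n_selected=%s mse=%.6g",
                        predictor, trait, test_env, strategy,
                        None if sel is None else sel.threshold_used,
                        None if sel is None else len(sel.selected_columns),
                        fold_mse,
                    )
                    if collect_details:
                        details[(predictor, trait, test_env, strategy)] = {
                            "selection": sel,
                            "predicted": pred.copy(),
                            "observed": obs_vals.copy(),
                        }
    return _assemble(pd.DataFrame(records), strategies, details)


def _assemble(records: pd.DataFrame, strategies, details) -> CVResult:
    """Pivot per-(fold, strategy) MSEs into report rows with REs."""
    if records.empty:
        empty = pd.DataFrame(columns=["predictor", "trait", "env"])
        return CVResult(empty, empty.copy(), details)
    wide = records.pivot_table(
        index=["predictor", "trait", "env"], columns="strategy", values="mse"
    ).reset_index().rename_axis(columns=None)
    rows = wide[["predictor", "trait", "env"]].copy()
    for strategy in strategies:
        rows[STRATEGY_MSE_COL[strategy]] = wide.get(strategy, np.nan)
    for col, (a, b) in RE_COLS.items():
        if a in strategies and b in strategies:
            rows[col] = wide[a] / wide[b]
    re_cols = [c for c in RE_COLS if c in rows.columns]
    if re_cols:
        across = (
            rows.groupby(["predictor", "trait"], as_index=False)[re_cols].mean()
        )
    else:
        across = rows[["predictor", "trait"]].drop_duplicates().reset_index(drop=True)
    return CVResult(rows, across, details)


def summary_table(cv: CVResult) -> pd.DataFrame:
    """Per-predictor summary: Across REs averaged over traits, plus Average.

    Mirrors a dataset-level summary table — an unweighted mean over traits
    of each predictor's Across REs, with a final row averaging the
    predictors.
    """
    re_cols = [c for c in RE_COLS if c in cv.across_rows.columns]
    per_pred = cv.across_rows.groupby("predictor", as_index=False)[re_cols].mean()
    avg = {"predictor": "Average"}
    for c in re_cols:
        avg[c] = per_pred[c].mean()
    return pd.concat([per_pred, pd.DataFrame([avg])], ignore_index=True)
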