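"""Feature engineering of environmental covariates.

New candidate covariates are generated from the measured ones by

* pairwise arithmetic on every unordered pair {a, b} (a before b in column
  order): sum a+b, difference a-b, product a*b and ratio a/b — one column
  per pair per operation, so at most ``4 * C(q, 2)`` pairwise columns; and
* unary transforms of each covariate: inverse 1/x, square x**2, sqrt(x),
  natural log, and Box-Cox power transforms ``(x**lam - 1)/lam`` for a
  small set of exponents.

Transforms that are undefined for a column's values (ratio or inverse with
a near-zero denominator, sqrt/log/Box-Cox of non-positives) are skipped —
never shifted — and the skip is logged, so engineered tables contain only
finite values.  The engineered table is the concatenation of the originals,
the pairwise block and the unary block, in a deterministic order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_data import EnvCovariateTable, ValidationError

__all__ = ["FEConfig", "pairwise_features", "unary_features", "engineer"]

PAIRWISE_OPS = ("add", "sub", "mul", "div")
UNARY_OPS = ("inverse", "square", "sqrt", "log", "boxcox")


@dataclass
class FEConfig:
    """Which transforms to apply and their numerical guards.

    ``boxcox_lambdas`` excludes 0 (the log transform covers it) and 1 (the
    identity).  The defaults {0.25, 0.75, 1.5} avoid lambdas in {-1, 0.5, 2}
    whose Box-Cox form differs from the explicit inverse/sqrt/square columns
    only by an affine map, which correlation-based selection cannot tell
    apart.
    """

    pairwise_ops: tuple[str, ...] = PAIRWISE_OPS
    unary_ops: tuple[str, ...] = UNARY_OPS
    boxcox_lambdas: tuple[float, ...] = (0.25, 0.75, 1.5)
    zero_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        bad = set(self.pairwise_ops) - set(PAIRWISE_OPS)
        if bad:
            raise ValueError(f"unknown pairwise ops: {sorted(bad)}")
        bad = set(self.unary_ops) - set(UNARY_OPS)
        if bad:
            raise ValueError(f"unknown unary ops: {sorted(bad)}")
        for lam in self.boxcox_lambdas:
            if lam in (0.0, 1.0):
                raise ValueError(
                    "boxcox lambda 0 (use log) and 1 (identity) are excluded"
                )


def _original_columns(W: EnvCovariateTable) -> list[str]:
    return [c for c in W.columns if W.provenance[c] == "original"]


def _require_all_original(W: EnvCovariateTable) -> None:
    engineered = [c for c in W.columns if W.provenance[c] != "original"]
    if engineered:
        raise ValidationError(
            f"non-original columns present: {engineered[:3]}{'...' if len(engineered) > 3 else ''}"
        )


def pairwise_features(W: EnvCovariateTable, cfg: FEConfig | None = None) -> EnvCovariateTable:
    """All pairwise arithmetic combinations of the original columns.

    Returns a table of new columns only.  Ratio columns a/b are emitted in
    one direction per pair and only when ``min |b|`` exceeds the zero
    tolerance; skipped ratios are noted in ``skip_log``.
    """
    cfg = cfg or FEConfig()
    _require_all_original(W)
    cols = _original_columns(W)
    out: dict[str, np.ndarray] = {}
    prov: dict[str, str] = {}
    skips: list[str] = []
    if len(cols) >= 2:
        for a, b in combinations(cols, 2):
            x, y = W.data[a].to_numpy(), W.data[b].to_numpy()
            for op in cfg.pairwise_ops:
                if op == "add":
                    vals = x + y
                elif op == "sub":
                    vals = x - y
                elif op == "mul":
                    vals = x * y
                elif op == "div":
                    if np.min(np.abs(y)) <= cfg.zero_tolerance:
                        skips.append(f"pairwise:div:{a}:{b} skipped (denominator ~0)")
                        continue
                    vals = x / y
                name = f"{op}({a},{b})"
                out[name] = vals
                prov[name] = f"pairwise:{op}:{a}:{b}"
    if not out:
        t = _empty_table(W)
        t.skip_log = skips
        return t
    df = pd.DataFrame(out, index=W.data.index, dtype=float)
    table = EnvCovariateTable(df, provenance=prov)
    table.skip_log = skips
    return table


def _empty_table(W: EnvCovariateTable) -> EnvCovariateTable:
    t = EnvCovariateTable.__new__(EnvCovariateTable)
    t.data = pd.DataFrame(index=W.data.index.copy(), dtype=float)
    t.provenance = {}
    t.skip_log = []
    return t


def unary_features(W: EnvCovariateTable, cfg: FEConfig | None = None) -> EnvCovariateTable:
    """Unary transforms of each original column.

    Square is always defined; inverse needs ``min |x|`` above the zero
    tolerance; sqrt, log and Box-Cox need strictly positive values.
    """
    cfg = cfg or FEConfig()
    _require_all_original(W)
    out: dict[str, np.ndarray] = {}
    prov: dict[str, str] = {}
    skips: list[str] = []
    for c in _original_columns(W):
        x = W.data[c].to_numpy()
        positive = bool(np.min(x) > 0)
        nonzero = bool(np.min(np.abs(x)) > cfg.zero_tolerance)
        for op in cfg.unary_ops:
            if op == "square":
                out[f"sq({c})"] = x**2
                prov[f"sq({c})"] = f"unary:square:{c}"
            elif op == "inverse":
                if not nonzero:
                    skips.append(f"unary:inverse:{c} skipped (values ~0)")
                    continue
                out[f"inv({c})"] = 1.0 / x
                prov[f"inv({c})"] = f"unary:inverse:{c}"
            elif op == "sqrt":
                if not positive:
                    skips.append(f"unary:sqrt:{c} skipped (non-positive values)")
                    continue
                out[f"sqrt({c})"] = np.sqrt(x)
                prov[f"sqrt({c})"] = f"unary:sqrt:{c}"
            elif op == "log":
                if not positive:
                    skips.append(f"unary:log:{c} skipped (non-positive values)")
                    continue
                out[f"log({c})"] = np.log(x)
                prov[f"log({c})"] = f"unary:log:{c}"
            elif op == "boxcox":
                if not positive:
                    skips.append(f"unary:boxcox:{c} skipped (non-positive values)")
                    continue
                for lam in cfg.boxcox_lambdas:
                    lam_tag = f"{lam:g}"
                    name = f"boxcox{lam_tag}({c})"
                    out[name] = (x**lam - 1.0) / lam
                    prov[name] = f"unary:boxcox{lam_tag}:{c}"
    if not out:
        t = _empty_table(W)
        t.skip_log = skips
        return t
    df = pd.DataFrame(out, index=W.data.index, dtype=float)
    table = EnvCovariateTable(df, provenance=prov)
    table.skip_log = skips
    return table


def engineer(W: EnvCovariateTable, cfg: FEConfig | None = None) -> EnvCovariateTable:
    """Concatenate originals, pairwise features and unary features.

    Raises if ``W`` already contains engineered columns — engineering is a
    single pass over measured covariates, never iterated.
    """
    cfg = cfg or FEConfig()
    _require_all_original(W)
    pw = pairwise_features(W, cfg)
    un = unary_features(W, cfg)
    parts = [W.data]
    prov = dict(W.provenance)
    for block in (pw, un):
        if len(block.data.columns):
            parts.append(block.data)
            prov.update(block.provenance)
    df = pd.concat(parts, axis=1)
    table = EnvCovariateTable(df, provenance=prov)
    table.skip_log = pw.skip_log + un.skip_log
    return table


def expected_column_count(q: int, n_lambdas: int) -> int:
    """Upper bound on engineered column count: q + 4*C(q,2) + q*(4 + n_lambdas)."""
    return q + 4 * math.comb(q, 2) + q * (4 + n_lambdas)
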