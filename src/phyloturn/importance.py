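"""Standardized regression of residual turnover on macroecological
characteristics and LMG (Shapley) variable-importance decomposition of R².

The LMG share of a regressor is its sequential R² contribution averaged
over all orderings in which the regressors can enter the model; shares are
non-negative and sum to the full-model R².  The production implementation
aggregates over the 2^p subsets with Shapley weights rather than looping
over p! orderings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "standardize",
    "lmg_importance",
    "ImportanceResult",
    "quadratic_design",
    "stratum_pair_predictors",
]


def standardize(x) -> np.ndarray:
    """Center to zero mean and scale to unit sample standard deviation."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    Xs = np.column_stack([np.ones(len(y)), X[:, cols]])
    coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    resid = y - Xs @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / sst


@dataclass
class ImportanceResult:
    """Full-model fit plus raw per-column LMG shares and per-variable
    importances rescaled to sum to 1."""

    r_squared: float
    raw_shares: dict[str, float]
    importance: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, imp in self.importance.items():
            raw_lin = self.raw_shares.get(var, 0.0)
            raw_quad = self.raw_shares.get(f"{var}^2", 0.0)
            rows.append(
                {
                    "variable": var,
                    "raw_linear": raw_lin,
                    "raw_quadratic": raw_quad,
                    "rescaled": imp,
                }
            )
        return pd.DataFrame(rows)


def lmg_importance(
    y,
    regressors: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> ImportanceResult:
    """LMG decomposition of R² over the given regressor columns.

    ``groups`` maps a variable name to the columns whose shares are summed
    for it (e.g. linear + quadratic term); by default every column is its
    own variable.  Importances are the grouped shares rescaled to sum to 1.
    """
    y = np.asarray(y, dtype=float)
    names = list(regressors.columns)
    X = regressors.to_numpy(dtype=float)
    p = len(names)
    if len(y) <= 2 * p:
        raise ValueError(f"need n > {2 * p} observations for {p} regressors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < p + 1:
        culprits = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
            )
            == p
        ]
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + (", ".join(culprits) if culprits else "(undetermined)")
        )
    # R² for every subset of columns, then Shapley-weighted marginal gains
    r2: dict[tuple[int, ...], float] = {(): 0.0}
    for size in range(1, p + 1):
        for cols in combinations(range(p), size):
            r2[cols] = _subset_r2(y, X, cols)
    weights = [
        math.factorial(s) * math.factorial(p - 1 - s) / math.factorial(p)
        for s in range(p)
    ]
    raw = {}
    for j in range(p):
        others = [i for i in range(p) if i != j]
        share = 0.0
        for size in range(p):
            for sub in combinations(others, size):
                with_j = tuple(sorted(sub + (j,)))
                share += weights[size] * (r2[with_j] - r2[sub])
        raw[names[j]] = share
    full_r2 = r2[tuple(range(p))]
    if groups is None:
        groups = {name: [name] for name in names}
    grouped = {
        var: sum(raw[col] for col in cols) for var, cols in groups.items()
    }
    total = sum(grouped.values())
    importance = {
        var: (val / total if total > 0 else float("nan"))
        for var, val in grouped.items()
    }
    return ImportanceResult(r_squared=full_r2, raw_shares=raw, importance=importance)


def quadratic_design(table: pd.DataFrame, variables: Sequence[str]) -> tuple[
    pd.DataFrame, dict[str, list[str]]
]:
    """Standardized linear + quadratic design matrix for the given columns.

    Quadratic terms are squares of the standardized linear terms, then
    standardized themselves.  Returns the design and the variable -> column
    grouping for :func:`lmg_importance`.
    """
    cols = {}
    groups: dict[str, list[str]] = {}
    for var in variables:
        z = standardize(table[var])
        cols[var] = z
        cols[f"{var}^2"] = standardize(z**2)
        groups[var] = [var, f"{var}^2"]
    return pd.DataFrame(cols), groups


def stratum_pair_predictors(
    pair_table: pd.DataFrame,
    macro: pd.DataFrame,
    sites_table: pd.DataFrame,
    variables: Sequence[str] = ("SR", "relPD", "NS"),
) -> pd.DataFrame:
    """Per-stratum-pair predictor values: the mean of the two strata's
    per-site means of each macroecological variable."""
    merged = macro.merge(sites_table[["site_id", "stratum"]], on="site_id")
    stratum_means = merged.groupby("stratum")[list(variables)].mean()
    rows = []
    for _, rec in pair_table.iterrows():
        va = stratum_means.loc[int(rec["stratum_a"])]
        vb = stratum_means.loc[int(rec["stratum_b"])]
        rows.append(0.5 * (va + vb))
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.insert(0, "stratum_a", pair_table["stratum_a"].to_numpy())
    out.insert(1, "stratum_b", pair_table["stratum_b"].to_numpy())
    return out
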