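"""Pairwise phylogenetic turnover over sites, distance residualization and
neighboring-strata aggregation.

Turnover between two assemblages is the Simpson (true turnover) component
measured on shared vs unique branch lengths, averaged over a set of trees.
The land-distance effect is removed with an OLS fit of logit-turnover on
distance (linear + quadratic); residuals stay on the logit scale.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .environment import SampleSites, StratificationLayer
from .trees import Phylogeny, phylo_simpson

logger = logging.getLogger(__name__)

__all__ = [
    "multi_tree_beta",
    "pairwise_beta_matrix",
    "multi_tree_beta_matrix",
    "build_records",
    "residualize_distance",
    "DistanceFit",
    "neighboring_strata_means",
]


def _check_communities(tree: Phylogeny, communities: Sequence[Iterable[str]]):
    tipset = set(tree.tips)
    for comm in communities:
        members = set(comm)
        if not members:
            raise ValueError("turnover is undefined for an empty community")
        missing = members - tipset
        if missing:
            raise ValueError(
                "community members missing from tree: " + ", ".join(sorted(missing))
            )


def multi_tree_beta(trees: Sequence[Phylogeny], comm1, comm2) -> float:
    """Mean phylogenetic Simpson turnover of one community pair over trees."""
    if not trees:
        raise ValueError("need at least one tree")
    for tree in trees:
        _check_communities(tree, [comm1, comm2])
    return float(np.mean([phylo_simpson(t, comm1, comm2) for t in trees]))


def pairwise_beta_matrix(
    tree: Phylogeny, communities: Sequence[Iterable[str]]
) -> np.ndarray:
    """Simpson turnover for all pairs of communities on one tree.

    Vectorized over the edge x community incidence; agrees with
    :func:`phylo_simpson` pair by pair (tested property).
    """
    _check_communities(tree, communities)
    inc = tree.edge_tip_incidence()
    tip_col = {label: j for j, label in enumerate(tree.tips)}
    member = np.zeros((tree.n_tips, len(communities)), dtype=bool)
    for s, comm in enumerate(communities):
        for label in comm:
            member[tip_col[label], s] = True
    touched = inc @ member  # (n_nodes, n_sites): edge on some member's path
    weighted = touched * tree.lengths[:, None]
    shared = weighted.T @ touched  # a_ij = shared branch length
    pd_site = np.diag(shared)
    b = pd_site[:, None] - shared
    c = pd_site[None, :] - shared
    m = np.minimum(b, c)
    denom = shared + m
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(m > 1e-12, m / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(beta, 0.0)
    return beta


def multi_tree_beta_matrix(
    trees: Sequence[Phylogeny], communities: Sequence[Iterable[str]]
) -> np.ndarray:
    """Mean of :func:`pairwise_beta_matrix` over a tree set."""
    if not trees:
        raise ValueError("need at least one tree")
    return np.mean([pairwise_beta_matrix(t, communities) for t in trees], axis=0)


def build_records(
    sites: SampleSites, beta: np.ndarray, dist_km: np.ndarray
) -> pd.DataFrame:
    """One row per unordered site pair: site_i, site_j, beta_raw, land_km."""
    n = len(sites)
    if beta.shape != (n, n) or dist_km.shape != (n, n):
        raise ValueError("matrix shapes do not match the site table")
    ids = sites.table["site_id"].to_numpy()
    i_idx, j_idx = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "site_i": ids[i_idx],
            "site_j": ids[j_idx],
            "beta_raw": beta[i_idx, j_idx],
            "land_km": dist_km[i_idx, j_idx],
        }
    )


@dataclass
class DistanceFit:
    """OLS fit of logit-turnover on land distance (linear + quadratic)."""

    intercept: float
    coef_linear: float
    coef_quadratic: float
    r_squared: float


def residualize_distance(
    records: pd.DataFrame, eps: float | None = None
) -> tuple[DistanceFit, pd.DataFrame]:
    """Fit ``logit(beta) ~ d + d^2`` by OLS and store per-pair residuals.

    Raw turnover is squeezed off {0,1} before the logit: by default with
    the n-dependent map ``(y*(n-1)+0.5)/n`` (n = number of pairs); if
    ``eps`` is given, with the fixed map ``y*(1-2*eps)+eps``.
    Returns the fit and a copy of ``records`` with ``beta_logit`` and
    ``residual`` columns filled.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 site pairs")
    beta = records["beta_raw"].to_numpy(dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta_raw outside [0, 1]")
    d = records["land_km"].to_numpy(dtype=float)
    if np.ptp(d) <= 0:
        raise ValueError("all distances equal: distance regression is rank-deficient")
    n = len(records)
    if eps is None:
        squeezed = (beta * (n - 1) + 0.5) / n
    else:
        if not 0 < eps < 0.5:
            raise ValueError("eps must lie in (0, 0.5)")
        squeezed = beta * (1 - 2 * eps) + eps
    y = np.log(squeezed / (1.0 - squeezed))
    X = sm.add_constant(np.column_stack([d, d**2]))
    fit = sm.OLS(y, X).fit()
    out = records.copy()
    out["beta_logit"] = y
    out["residual"] = fit.resid
    return (
        DistanceFit(
            intercept=float(fit.params[0]),
            coef_linear=float(fit.params[1]),
            coef_quadratic=float(fit.params[2]),
            r_squared=float(fit.rsquared),
        ),
        out,
    )


def _adjacent(si: int, sj: int, k: int, adjacency: str) -> bool:
    ai, aj = divmod(si, k)
    bi, bj = divmod(sj, k)
    di, dj = abs(ai - bi), abs(aj - bj)
    if adjacency == "rook":
        return di + dj == 1
    if adjacency == "queen":
        return max(di, dj) == 1
    raise ValueError(f"unknown adjacency {adjacency!r}")


def neighboring_strata_means(
    records: pd.DataFrame,
    sites: SampleSites,
    strata: StratificationLayer,
    adjacency: str = "rook",
    value: str = "residual",
) -> pd.DataFrame:
    """Mean residual turnover between every populated pair of neighboring
    strata, with the pair's midpoint in (env1, env2) space.

    Only cross-stratum site pairs contribute; strata are neighbors when
    their class indices are adjacent in the k x k stratification grid.
    """
    if value not in records.columns:
        raise ValueError(f"records lack a {value!r} column")
    stratum_of = dict(
        zip(sites.table["site_id"], sites.table["stratum"].astype(int))
    )
    present = sorted(set(stratum_of.values()))
    rec_si = records["site_i"].map(stratum_of).to_numpy()
    rec_sj = records["site_j"].map(stratum_of).to_numpy()
    vals = records[value].to_numpy(dtype=float)
    rows = []
    for sa, sb in itertools.combinations(present, 2):
        if not _adjacent(sa, sb, strata.k, adjacency):
            continue
        cross = ((rec_si == sa) & (rec_sj == sb)) | (
            (rec_si == sb) & (rec_sj == sa)
        )
        n_pairs = int(cross.sum())
        if n_pairs == 0:
            continue
        ca = strata.stratum_center(sa)
        cb = strata.stratum_center(sb)
        rows.append(
            {
                "stratum_a": sa,
                "stratum_b": sb,
                "env1_mid": 0.5 * (ca[0] + cb[0]),
                "env2_mid": 0.5 * (ca[1] + cb[1]),
                "mean_residual": float(vals[cross].mean()),
                "n_pairs": n_pairs,
            }
        )
    if not rows:
        raise ValueError("no adjacent stratum pair is populated with sites")
    return pd.DataFrame(rows)
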