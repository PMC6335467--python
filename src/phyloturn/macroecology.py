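"""Per-site macroecological characteristics: species richness, Faith's PD,
relative phylogenetic diversity and realized niche size.

Relative PD is the residual of PD regressed on richness (linear +
quadratic).  Niche size is the area of the 95% bivariate data ellipse of a
species' occupied cells in (env1, env2) space, aggregated per site as the
mean over present species.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .environment import EnvRaster, OccurrenceGrid, SampleSites
from .trees import Phylogeny, faith_pd

logger = logging.getLogger(__name__)

__all__ = [
    "relative_pd",
    "niche_ellipse_area",
    "species_niche_areas",
    "site_niche_size",
    "macroeco_table",
]


def relative_pd(sr: Sequence[int], pd_values: Sequence[float]) -> np.ndarray:
    """Residuals of OLS ``PD ~ SR + SR^2``, in input order.

    Positive values flag sites holding more divergent lineages than their
    richness predicts; negative values flag radiations of close relatives.
    """
    sr = np.asarray(sr, dtype=float)
    pdv = np.asarray(pd_values, dtype=float)
    if sr.size != pdv.size or sr.size < 4:
        raise ValueError("need >= 4 paired SR/PD values")
    if np.ptp(sr) <= 0:
        raise ValueError("species richness is constant: regression is rank-deficient")
    X = sm.add_constant(np.column_stack([sr, sr**2]))
    fit = sm.OLS(pdv, X).fit()
    return np.asarray(fit.resid)


def niche_ellipse_area(
    points: Sequence[tuple[float, float]], coverage: float = 0.95
) -> float:
    """Area of the bivariate data ellipse covering ``coverage`` of the
    points in expectation: ``pi * sqrt(det(S)) * chi2.ppf(coverage, 2)``
    with S the sample covariance.

    Returns NaN (with a warning) for < 3 points or a singular covariance.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 3:
        logger.warning("niche undefined: fewer than 3 points")
        return float("nan")
    cov = np.cov(pts, rowvar=False)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.isfinite(det):
        logger.warning("niche undefined: singular covariance (collinear points)")
        return float("nan")
    return float(np.pi * np.sqrt(det) * chi2.ppf(coverage, df=2))


def species_niche_areas(
    occ: OccurrenceGrid,
    env1: EnvRaster,
    env2: EnvRaster,
    coverage: float = 0.95,
) -> dict[str, float]:
    """Niche ellipse area per species from its occupied land cells."""
    land = env1.land_mask & env2.land_mask
    areas: dict[str, float] = {}
    for i, sp in enumerate(occ.species):
        cells = occ.presence[i] & land
        pts = np.column_stack([env1.values[cells], env2.values[cells]])
        areas[sp] = niche_ellipse_area(pts, coverage) if len(pts) >= 3 else float("nan")
    return areas


def site_niche_size(
    community: Iterable[str],
    per_species_area: Mapping[str, float],
    how: str = "mean",
) -> float:
    """Aggregate member niche areas per site; undefined areas are skipped."""
    areas = [
        per_species_area[sp]
        for sp in community
        if sp in per_species_area and np.isfinite(per_species_area[sp])
    ]
    if not areas:
        logger.warning("site niche size undefined: no member with a defined area")
        return float("nan")
    if how == "mean":
        return float(np.mean(areas))
    if how == "median":
        return float(np.median(areas))
    raise ValueError(f"unknown aggregation {how!r}")


def macroeco_table(
    sites: SampleSites,
    trees: Sequence[Phylogeny],
    occ: OccurrenceGrid,
    env1: EnvRaster,
    env2: EnvRaster,
    coverage: float = 0.95,
    ns_aggregation: str = "mean",
) -> pd.DataFrame:
    """Site table with columns site_id, SR, PD, relPD, NS.

    PD is Faith's rooted PD averaged over the tree set; NS uses each
    species' occupied cells over the whole study area.
    """
    communities = sites.communities
    if communities is None:
        communities = occ.communities_at(sites.table["row"], sites.table["col"])
    areas = species_niche_areas(occ, env1, env2, coverage)
    sr = np.array([len(c) for c in communities], dtype=int)
    pd_vals = np.array(
        [np.mean([faith_pd(t, c) for t in trees]) for c in communities]
    )
    ns = np.array([site_niche_size(c, areas, ns_aggregation) for c in communities])
    table = pd.DataFrame(
        {
            "site_id": sites.table["site_id"].to_numpy(),
            "SR": sr,
            "PD": pd_vals,
            "relPD": relative_pd(sr, pd_vals),
            "NS": ns,
        }
    )
    return table
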