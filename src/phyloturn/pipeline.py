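"""Config-driven end-to-end orchestration.

Stages: generate/ingest -> stratify -> sample -> land distances ->
pairwise turnover (per delta / truncation depth) -> distance
residualization -> neighboring-strata means -> macroecology ->
environmental-space surfaces -> LMG importance.  Sites and distances are
shared across all delta/truncation variants (they do not depend on the
tree); every stochastic draw derives from the single run seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environment import (EnvRaster, OccurrenceGrid, SampleSites,
                          allocate_samples, read_ascii_grid, stratify,
                          write_ascii_grid)
from .geodistance import CostSurface, euclidean_distances, pairwise_land_distances
from .importance import lmg_importance, quadratic_design, stratum_pair_predictors
from .interpolation import rasterize_env
from .macroecology import macroeco_table
from .synthetic import SyntheticConfig, simulate_dataset
from .trees import (Phylogeny, delta_transform, read_newick_trees,
                    truncate_tree, write_newick_trees)
from .turnover import (build_records, multi_tree_beta_matrix,
                       neighboring_strata_means, pairwise_beta_matrix,
                       residualize_distance)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs.

    Either ``synthetic`` or the four input paths must be provided.
    Defaults follow the reference settings: 9x9 strata, 1-10 sites per
    stratum, deltas {0.1, 0.3, 1, 3, 10}, sea penalty 10, 20 trees.
    """

    synthetic: SyntheticConfig | None = None
    env1_path: str | None = None
    env2_path: str | None = None
    trees_path: str | None = None
    occurrence_path: str | None = None
    k: int = 9
    min_n: int = 1
    max_n: int = 10
    deltas: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)
    truncation_depths: tuple[float, ...] = ()
    sea_penalty: float | str = 10.0
    connectivity: int = 8
    n_trees: int = 20
    adjacency: str = "rook"
    surface_shape: tuple[int, int] = (50, 50)
    rooted_pd: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if "synthetic" in data and data["synthetic"] is not None:
            data["synthetic"] = SyntheticConfig(**data["synthetic"])
        for key in ("deltas", "truncation_depths", "surface_shape"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        ds = simulate_dataset(cfg.synthetic)
        return ds.env1, ds.env2, ds.trees, ds.occurrences
    missing = [
        name
        for name, val in (
            ("env1_path", cfg.env1_path),
            ("env2_path", cfg.env2_path),
            ("trees_path", cfg.trees_path),
            ("occurrence_path", cfg.occurrence_path),
        )
        if val is None
    ]
    if missing:
        raise ValueError(
            "config must set either synthetic or all input paths; missing: "
            + ", ".join(missing)
        )
    return (
        read_ascii_grid(cfg.env1_path),
        read_ascii_grid(cfg.env2_path),
        read_newick_trees(cfg.trees_path),
        OccurrenceGrid.from_csv(cfg.occurrence_path),
    )


def _delta_dir(outdir: Path, delta: float) -> Path:
    return outdir / f"delta_{delta:g}"


def _write_surface(points, shape, path) -> bool:
    try:
        surf = rasterize_env(points, shape)
    except ValueError as exc:
        logger.warning("surface %s skipped: %s", path.name, exc)
        return False
    surf.to_csv(path)
    return True


def _turnover_stage(
    stage_dir: Path,
    beta: np.ndarray,
    sites: SampleSites,
    dist: np.ndarray,
    strat,
    cfg: RunConfig,
) -> pd.DataFrame | None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    records = build_records(sites, beta, dist)
    fit, records = residualize_distance(records)
    records.to_csv(stage_dir / "records.csv", index=False)
    with open(stage_dir / "distance_fit.json", "w") as fh:
        json.dump(dataclasses.asdict(fit), fh, indent=2)
    pairs = neighboring_strata_means(records, sites, strat, cfg.adjacency)
    pairs.to_csv(stage_dir / "stratum_pairs.csv", index=False)
    _write_surface(
        pairs[["env1_mid", "env2_mid", "mean_residual"]].to_numpy(),
        cfg.surface_shape,
        stage_dir / "surface_residual.csv",
    )
    return pairs


def run_pipeline(cfg: RunConfig, outdir) -> dict[str, Any]:
    """Run every stage and write artifacts under ``outdir``.

    Returns a summary dict with the key tables in memory.  Outputs are a
    pure function of (inputs, config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env1, env2, trees, occ = _load_inputs(cfg)
    trees = trees[: cfg.n_trees]
    if cfg.synthetic is not None:
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        write_ascii_grid(env1, inputs_dir / "env1.asc")
        write_ascii_grid(env2, inputs_dir / "env2.asc")
        write_newick_trees(trees, inputs_dir / "trees.nwk")
        occ.to_csv(inputs_dir / "occurrence.csv")

    logger.info("stratifying into %d x %d classes", cfg.k, cfg.k)
    strat = stratify(env1, env2, cfg.k)
    sites = allocate_samples(
        strat, env1, env2, occ.occupancy(),
        min_n=cfg.min_n, max_n=cfg.max_n, seed=cfg.seed, occurrences=occ,
    )
    logger.info("sampled %d sites in %d strata", len(sites),
                sites.table["stratum"].nunique())
    sites.to_csv(outdir / "sites.csv")

    if cfg.sea_penalty == "euclidean":
        dist = euclidean_distances(sites, env1.resolution_km)
    else:
        surface = CostSurface.from_land_mask(
            env1.land_mask | env2.land_mask,
            sea_penalty=float(cfg.sea_penalty),
            resolution_km=env1.resolution_km,
            connectivity=cfg.connectivity,
        )
        dist = pairwise_land_distances(surface, sites)
    pd.DataFrame(dist).to_csv(outdir / "distance_matrix.csv", index=False)

    communities = sites.communities
    summary: dict[str, Any] = {"sites": sites, "n_sites": len(sites)}
    for delta in cfg.deltas:
        ddir = _delta_dir(outdir, delta)
        logger.info("delta = %g", delta)
        dtrees = (
            trees if delta == 1.0 else [delta_transform(t, delta) for t in trees]
        )
        beta = multi_tree_beta_matrix(dtrees, communities)
        pairs = _turnover_stage(ddir, beta, sites, dist, strat, cfg)
        macro = macroeco_table(sites, dtrees, occ, env1, env2)
        macro.to_csv(ddir / "macroeco.csv", index=False)
        site_pts = sites.table[["env1", "env2"]].to_numpy()
        for var in ("SR", "relPD", "NS"):
            vals = macro[var].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            _write_surface(
                np.column_stack([site_pts[ok], vals[ok]]),
                cfg.surface_shape,
                ddir / f"surface_{var}.csv",
            )
        if pairs is not None:
            predictors = stratum_pair_predictors(pairs, macro, sites.table)
            design_src = predictors[["SR", "relPD", "NS"]].dropna()
            y = pairs.loc[design_src.index, "mean_residual"].to_numpy()
            if len(design_src) > 12:
                design, groups = quadratic_design(design_src, ("SR", "relPD", "NS"))
                result = lmg_importance(y, design, groups)
                frame = result.to_frame()
                frame["r_squared"] = result.r_squared
                frame.to_csv(ddir / "importance.csv", index=False)
                summary[f"importance_delta_{delta:g}"] = result
            else:
                logger.warning(
                    "delta %g: only %d stratum pairs; importance skipped",
                    delta, len(design_src),
                )
        summary[f"pairs_delta_{delta:g}"] = pairs

    for depth in cfg.truncation_depths:
        tdir = outdir / f"depth_{depth:g}"
        logger.info("truncation depth = %g", depth)
        betas = []
        for tree in trees:
            ttree, mapping = truncate_tree(tree, depth)
            occ_t = occ.collapse(mapping)
            comms_t = occ_t.communities_at(sites.table["row"], sites.table["col"])
            betas.append(pairwise_beta_matrix(ttree, comms_t))
        _turnover_stage(tdir, np.mean(betas, axis=0), sites, dist, strat, cfg)

    manifest = {
        "phyloturn_version": __version__,
        "config": _jsonable(cfg.to_dict()),
        "n_sites": len(sites),
        "n_trees_used": len(trees),
        "artifacts": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    summary["manifest"] = manifest
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
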