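"""Synthetic study systems with known structure.

Generates everything the pipeline consumes: a gridded land/sea study
area, two correlated environmental gradients, dated (Yule) phylogenies,
Brownian-motion niche evolution, and threshold-based Gaussian-suitability
species ranges.  Scenario builders plant known turnover structure (a
two-clade barrier on the env1 gradient) for end-to-end checks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .environment import EnvRaster, OccurrenceGrid
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_tree",
    "evolve_niches",
    "build_ranges",
    "crossed_gradients",
    "simulate_landscape",
    "simulate_dataset",
    "planted_barrier_dataset",
]


@dataclass
class SyntheticConfig:
    """Knobs for a fully synthetic study system."""

    rows: int = 40
    cols: int = 40
    sea_fraction: float = 0.1
    n_species: int = 40
    birth_rate: float = 1.0
    niche_sigma2: float = 0.05
    niche_breadth: tuple[float, float] = (0.18, 0.25)
    suitability_threshold: float = 0.5
    env_correlation: float = 0.3
    n_trees: int = 5
    resolution_km: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sea_fraction < 1:
            raise ValueError("sea_fraction must lie in [0, 1)")
        if self.n_species < 2 or self.birth_rate <= 0 or self.niche_sigma2 < 0:
            raise ValueError("invalid synthetic configuration")


@dataclass
class SyntheticDataset:
    env1: EnvRaster
    env2: EnvRaster
    trees: list[Phylogeny]
    occurrences: OccurrenceGrid
    niche_centers: dict[str, tuple[float, float]] = field(default_factory=dict)


# ----------------------------------------------------------------------
# Trees and niches
# ----------------------------------------------------------------------

def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> Phylogeny:
    """Yule (pure-birth) tree with exactly ``n_species`` tips, ultrametric
    and normalized to unit height.  Deterministic given the seed."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if labels is not None and len(labels) != n_species:
        raise ValueError("label count must equal n_species")
    rng = np.random.default_rng(seed)
    parent = [-1]
    times = [0.0]
    # open lineages: (parent node id, start time); the root splits at t=0
    open_lineages = [(0, 0.0), (0, 0.0)]
    t = 0.0
    while len(open_lineages) < n_species:
        k = len(open_lineages)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        p, _ = open_lineages.pop(i)
        node = len(parent)
        parent.append(p)
        times.append(t)
        open_lineages.append((node, t))
        open_lineages.append((node, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    node_labels: list[str | None] = [None] * len(parent)
    for j, (p, _) in enumerate(open_lineages):
        parent.append(p)
        times.append(t_end)
        node_labels.append(
            labels[j] if labels is not None else f"sp{j:04d}"
        )
    times_arr = np.asarray(times) / t_end  # unit height
    parent_arr = np.asarray(parent)
    lengths = times_arr - times_arr[np.maximum(parent_arr, 0)]
    lengths[0] = 0.0
    return Phylogeny(parent_arr, lengths, node_labels)


def evolve_niches(
    tree: Phylogeny,
    sigma2: float,
    root_center: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Brownian motion of a 2-D niche center along the tree's branches
    (independent axes, variance ``sigma2`` per unit branch length)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values = np.zeros((tree.n_nodes, 2))
    values[0] = root_center
    for i in range(1, tree.n_nodes):
        step = rng.normal(0.0, np.sqrt(sigma2 * tree.lengths[i]), size=2)
        values[i] = values[tree.parent[i]] + step
    return {
        tree.labels[i]: (float(values[i, 0]), float(values[i, 1]))
        for i in tree.tip_nodes
    }


def build_ranges(
    centers: Mapping[str, tuple[float, float]],
    breadths,
    env1: EnvRaster,
    env2: EnvRaster,
    threshold: float = 0.5,
) -> OccurrenceGrid:
    """Presence wherever the axis-aligned Gaussian suitability
    ``exp(-[(e1-c1)^2/(2 b1^2) + (e2-c2)^2/(2 b2^2)])`` reaches the
    threshold.  Species ending up with zero occupied cells are dropped
    with a warning."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    land = env1.land_mask & env2.land_mask
    species: list[str] = []
    layers: list[np.ndarray] = []
    for sp in centers:
        c1, c2 = centers[sp]
        b1, b2 = breadths[sp] if isinstance(breadths, Mapping) else breadths
        if b1 <= 0 or b2 <= 0:
            raise ValueError("niche breadths must be positive")
        with np.errstate(invalid="ignore"):
            expo = ((env1.values - c1) ** 2) / (2 * b1**2) + (
                (env2.values - c2) ** 2
            ) / (2 * b2**2)
            suit = np.exp(-expo)
        present = land & (suit >= threshold)
        if not present.any():
            logger.warning("species %s has no suitable cell; dropped", sp)
            continue
        species.append(sp)
        layers.append(present)
    if not species:
        raise ValueError("no species retained any range")
    return OccurrenceGrid(species, np.stack(layers))


# ----------------------------------------------------------------------
# Landscapes
# ----------------------------------------------------------------------

def crossed_gradients(
    rows: int, cols: int, resolution_km: float = 15.0
) -> tuple[EnvRaster, EnvRaster]:
    """All-land grid with env1 varying along rows and env2 along columns,
    each spanning [0, 1] — every class combination of an equal-width
    stratification is occupied."""
    g1 = np.repeat(np.linspace(0.0, 1.0, rows)[:, None], cols, axis=1)
    g2 = np.repeat(np.linspace(0.0, 1.0, cols)[None, :], rows, axis=0)
    land = np.ones((rows, cols), dtype=bool)
    return (
        EnvRaster(g1, land, resolution_km),
        EnvRaster(g2, land, resolution_km),
    )


def simulate_landscape(
    rows: int,
    cols: int,
    sea_fraction: float = 0.1,
    correlation: float = 0.3,
    seed: int = 0,
    resolution_km: float = 15.0,
) -> tuple[EnvRaster, EnvRaster]:
    """Smoothed random land mask plus two correlated gradients in [0, 1]:
    env1 follows rows, env2 mixes the column gradient with env1."""
    rng = np.random.default_rng(seed)
    g_row = np.repeat(np.linspace(0.0, 1.0, rows)[:, None], cols, axis=1)
    g_col = np.repeat(np.linspace(0.0, 1.0, cols)[None, :], rows, axis=0)
    noise1 = gaussian_filter(rng.normal(size=(rows, cols)), sigma=3.0)
    noise2 = gaussian_filter(rng.normal(size=(rows, cols)), sigma=3.0)
    env1 = g_row + 0.1 * noise1
    env2 = (1 - abs(correlation)) * g_col + correlation * g_row + 0.1 * noise2
    if sea_fraction > 0:
        sea_field = gaussian_filter(rng.normal(size=(rows, cols)), sigma=3.0)
        land = sea_field > np.quantile(sea_field, sea_fraction)
    else:
        land = np.ones((rows, cols), dtype=bool)

    def _norm(grid: np.ndarray) -> np.ndarray:
        vals = grid[land]
        out = (grid - vals.min()) / (vals.max() - vals.min())
        return np.where(land, out, np.nan)

    return (
        EnvRaster(_norm(env1), land, resolution_km),
        EnvRaster(_norm(env2), land, resolution_km),
    )


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic study system; replicate trees emulate phylogenetic
    uncertainty (independent Yule draws over the same species set)."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3 + cfg.n_trees)
    env1, env2 = simulate_landscape(
        cfg.rows, cfg.cols, cfg.sea_fraction, cfg.env_correlation,
        seed=int(seeds[0]), resolution_km=cfg.resolution_km,
    )
    labels = [f"sp{j:04d}" for j in range(cfg.n_species)]
    trees = [
        simulate_tree(cfg.n_species, cfg.birth_rate, seed=int(seeds[3 + j]),
                      labels=labels)
        for j in range(cfg.n_trees)
    ]
    centers = evolve_niches(
        trees[0], cfg.niche_sigma2, root_center=(0.5, 0.5), seed=int(seeds[1])
    )
    occ = build_ranges(
        centers, cfg.niche_breadth, env1, env2, cfg.suitability_threshold
    )
    return SyntheticDataset(env1, env2, trees, occ, centers)


# ----------------------------------------------------------------------
# Planted-barrier scenarios (end-to-end checks)
# ----------------------------------------------------------------------

def _scale_lengths(tree: Phylogeny, factor: float) -> Phylogeny:
    return Phylogeny(tree.parent, tree.lengths * factor, tree.labels)


def _two_clade_tree(n_per_side: int, seed: int) -> Phylogeny:
    """Deep barrier: two Yule clades of height 0.5 joined by 0.5 stems."""
    ss = np.random.SeedSequence(seed).generate_state(2)
    left = _scale_lengths(
        simulate_tree(n_per_side, seed=int(ss[0]),
                      labels=[f"L{j:02d}" for j in range(n_per_side)]),
        0.5,
    )
    right = _scale_lengths(
        simulate_tree(n_per_side, seed=int(ss[1]),
                      labels=[f"R{j:02d}" for j in range(n_per_side)]),
        0.5,
    )
    parent: list[int] = [-1]
    lengths: list[float] = [0.0]
    labels: list[str | None] = [None]
    for sub in (left, right):
        offset = len(parent)
        for i in range(sub.n_nodes):
            parent.append(0 if i == 0 else offset + int(sub.parent[i]))
            lengths.append(0.5 if i == 0 else float(sub.lengths[i]))
            labels.append(sub.labels[i])
    return Phylogeny(parent, lengths, labels)


def _cherry_tree(n_pairs: int, seed: int, split_depth: float = 0.85) -> Phylogeny:
    """Shallow barrier: each of ``n_pairs`` lineages splits into an L/R
    cherry at ``split_depth`` of the unit tree height."""
    base = _scale_lengths(
        simulate_tree(n_pairs, seed=seed,
                      labels=[f"anc{j:02d}" for j in range(n_pairs)]),
        split_depth,
    )
    parent = list(base.parent)
    lengths = list(base.lengths)
    labels: list[str | None] = [None if i in set(base.tip_nodes) else base.labels[i]
                                 for i in range(base.n_nodes)]
    tip_len = 1.0 - split_depth
    for j, node in enumerate(base.tip_nodes):
        for side in ("L", "R"):
            parent.append(int(node))
            lengths.append(tip_len)
            labels.append(f"{side}{j:02d}")
    return Phylogeny(parent, lengths, labels)


def planted_barrier_dataset(
    seed: int,
    barrier: str = "basal",
    n_per_side: int = 12,
    rows: int = 30,
    cols: int = 30,
    resolution_km: float = 15.0,
) -> SyntheticDataset:
    """Two species groups confined to the two halves of the env1 gradient,
    separated by either a basal split ("basal") or by recent per-pair
    splits ("recent").  The turnover barrier sits at env1 = 0.5."""
    rng = np.random.default_rng(seed)
    env1, env2 = crossed_gradients(rows, cols, resolution_km)
    if barrier == "basal":
        tree = _two_clade_tree(n_per_side, seed)
        mean_left, mean_right, b1 = 0.27, 0.73, 0.15
    elif barrier == "recent":
        tree = _cherry_tree(n_per_side, seed)
        mean_left, mean_right, b1 = 0.32, 0.68, 0.13
    else:
        raise ValueError("barrier must be 'basal' or 'recent'")
    env2_spots = np.linspace(0.1, 0.9, n_per_side)
    centers: dict[str, tuple[float, float]] = {}
    for j in range(n_per_side):
        jitter = rng.normal(0.0, 0.03, size=4)
        centers[f"L{j:02d}"] = (
            float(np.clip(mean_left + jitter[0], 0.05, 0.45)),
            float(np.clip(env2_spots[j] + jitter[1], 0.0, 1.0)),
        )
        centers[f"R{j:02d}"] = (
            float(np.clip(mean_right + jitter[2], 0.55, 0.95)),
            float(np.clip(env2_spots[j] + jitter[3], 0.0, 1.0)),
        )
    occ = build_ranges(centers, (b1, 0.45), env1, env2, threshold=0.5)
    return SyntheticDataset(env1, env2, [tree], occ, centers)
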