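"""Least-cost geographic land distance over the study grid.

Sea cells are traversable but expensive (default 10x land cost).  A step
between adjacent cells costs ``resolution_km * step_factor * (cost_u +
cost_v) / 2`` with ``step_factor = 1`` for rook moves and ``sqrt(2)`` for
diagonal moves; paths are 8-connected by default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = ["CostSurface", "land_distance", "pairwise_land_distances",
           "euclidean_distances"]


@dataclass
class CostSurface:
    """Per-cell traversal cost multiplier (1 on land, ``penalty`` on sea)."""

    cost: np.ndarray
    resolution_km: float = 15.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.ndim != 2:
            raise ValueError("cost must be a 2-D grid")
        if np.any(~np.isfinite(self.cost)) or np.any(self.cost < 1.0):
            raise ValueError("cell costs must be finite and >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @classmethod
    def from_land_mask(
        cls,
        land_mask: np.ndarray,
        sea_penalty: float = 10.0,
        resolution_km: float = 15.0,
        connectivity: int = 8,
    ) -> "CostSurface":
        if sea_penalty < 1.0:
            raise ValueError("sea penalty must be >= 1")
        cost = np.where(np.asarray(land_mask, dtype=bool), 1.0, float(sea_penalty))
        return cls(cost, resolution_km, connectivity)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cost.shape

    def graph(self):
        """Sparse upper-half adjacency; scipy's dijkstra with
        ``directed=False`` treats each stored edge as bidirectional."""
        rows, cols = self.shape
        idx = np.arange(rows * cols).reshape(rows, cols)
        res = self.resolution_km
        cost = self.cost
        us, vs, ws = [], [], []

        def add(u, v, w):
            us.append(u.ravel())
            vs.append(v.ravel())
            ws.append(w.ravel())

        # rook moves
        add(idx[:, :-1], idx[:, 1:], res * 0.5 * (cost[:, :-1] + cost[:, 1:]))
        add(idx[:-1, :], idx[1:, :], res * 0.5 * (cost[:-1, :] + cost[1:, :]))
        if self.connectivity == 8:
            diag = res * np.sqrt(2.0)
            add(idx[:-1, :-1], idx[1:, 1:],
                diag * 0.5 * (cost[:-1, :-1] + cost[1:, 1:]))
            add(idx[:-1, 1:], idx[1:, :-1],
                diag * 0.5 * (cost[:-1, 1:] + cost[1:, :-1]))
        u = np.concatenate(us)
        v = np.concatenate(vs)
        w = np.concatenate(ws)
        n = rows * cols
        return coo_matrix((w, (u, v)), shape=(n, n)).tocsr()

    def _node(self, cell) -> int:
        r, c = int(cell[0]), int(cell[1])
        rows, cols = self.shape
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"cell {cell} outside {rows}x{cols} grid")
        return r * cols + c


def _cells_of(sites) -> list[tuple[int, int]]:
    """Accept a SampleSites, a DataFrame with row/col, or a cell sequence."""
    table = getattr(sites, "table", sites)
    if hasattr(table, "columns"):
        return list(zip(table["row"].astype(int), table["col"].astype(int)))
    return [(int(r), int(c)) for r, c in table]


def pairwise_land_distances(surface: CostSurface, sites) -> np.ndarray:
    """Symmetric matrix of least-cost distances (km) between site cells."""
    cells = _cells_of(sites)
    if len(cells) < 2:
        raise ValueError("need at least 2 sites")
    nodes = np.array([surface._node(c) for c in cells])
    dist = dijkstra(surface.graph(), directed=False, indices=nodes)
    mat = dist[:, nodes]
    return 0.5 * (mat + mat.T)  # symmetrize away float noise


def land_distance(surface: CostSurface, site_a, site_b) -> float:
    """Least-cost distance (km) between two cells."""
    a = surface._node(site_a)
    b = surface._node(site_b)
    if a == b:
        return 0.0
    dist = dijkstra(surface.graph(), directed=False, indices=[a])
    return float(dist[0, b])


def euclidean_distances(sites, resolution_km: float = 15.0) -> np.ndarray:
    """Straight-line cell-center distances (km), the no-penalty fallback."""
    cells = np.asarray(_cells_of(sites), dtype=float)
    diff = cells[:, None, :] - cells[None, :, :]
    return resolution_km * np.hypot(diff[..., 0], diff[..., 1])
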