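"""Rasterize scattered values onto a regular grid over environmental space.

Piecewise-linear (Delaunay) interpolation generalizes bilinear
interpolation to irregular input positions: on a regular input lattice the
two coincide.  Nodes outside the convex hull of the inputs stay undefined
(NaN) — no extrapolation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.spatial import QhullError

__all__ = ["EnvSurface", "rasterize_env"]


@dataclass
class EnvSurface:
    """Regular grid over (env1, env2) holding an interpolated quantity."""

    axis1: np.ndarray  # grid coordinates along env1
    axis2: np.ndarray  # grid coordinates along env2
    values: np.ndarray  # shape (len(axis1), len(axis2)); NaN outside hull

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (env1, env2, value)."""
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {"env1": a1.ravel(), "env2": a2.ravel(), "value": self.values.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnvSurface":
        df = pd.read_csv(path)
        axis1 = np.unique(df["env1"].to_numpy())
        axis2 = np.unique(df["env2"].to_numpy())
        values = (
            df.pivot(index="env1", columns="env2", values="value")
            .reindex(index=axis1, columns=axis2)
            .to_numpy()
        )
        return cls(axis1, axis2, values)


def rasterize_env(
    points: Sequence[tuple[float, float, float]],
    grid_shape: tuple[int, int] = (50, 50),
) -> EnvSurface:
    """Interpolate scattered ``(env1, env2, value)`` points onto a regular
    grid spanning their bounding box.

    Values at grid nodes come from triangulation-based linear
    interpolation; nodes outside the convex hull are NaN.  Input values
    are reproduced exactly at input coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need >= 3 points of (env1, env2, value)")
    n1, n2 = grid_shape
    if n1 < 2 or n2 < 2:
        raise ValueError("grid_shape must be at least (2, 2)")
    xy = pts[:, :2]
    if np.linalg.matrix_rank(xy - xy.mean(axis=0), tol=1e-12) < 2:
        raise ValueError("input points are collinear; cannot triangulate")
    axis1 = np.linspace(xy[:, 0].min(), xy[:, 0].max(), n1)
    axis2 = np.linspace(xy[:, 1].min(), xy[:, 1].max(), n2)
    g1, g2 = np.meshgrid(axis1, axis2, indexing="ij")
    try:
        values = griddata(xy, pts[:, 2], (g1, g2), method="linear")
    except QhullError as exc:  # degenerate geometry qhull catches late
        raise ValueError(f"triangulation failed: {exc}") from exc
    return EnvSurface(axis1, axis2, values)
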