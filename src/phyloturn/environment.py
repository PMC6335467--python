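"""Environmental layers, stratification and stratified random site sampling.

Rasters are plain 2-D arrays with a boolean land mask; file I/O uses the
ESRI ASCII grid format (text only).  Cell indexing is 0-based ``(row, col)``
with distances measured between cell centers.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EnvRaster",
    "StratificationLayer",
    "SampleSites",
    "OccurrenceGrid",
    "turc_pet",
    "moisture_index",
    "stratify",
    "allocate_samples",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class EnvRaster:
    """A gridded environmental variable restricted to land cells.

    ``values`` holds the variable (NaN over sea), ``land_mask`` is True on
    land, ``resolution_km`` is the cell size.
    """

    values: np.ndarray
    land_mask: np.ndarray
    resolution_km: float = 15.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.values.shape != self.land_mask.shape:
            raise ValueError("values and land_mask shapes differ")
        if self.resolution_km <= 0:
            raise ValueError("resolution_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def land_values(self) -> np.ndarray:
        return self.values[self.land_mask]


@dataclass
class StratificationLayer:
    """Combined stratum id per land cell from crossing two equal-width
    classifications of k classes each: ``id = class1 * k + class2``.

    Cells outside the study area carry id -1.
    """

    stratum_id: np.ndarray
    breaks1: np.ndarray
    breaks2: np.ndarray
    k: int

    def class_centers(self, axis: int) -> np.ndarray:
        breaks = self.breaks1 if axis == 0 else self.breaks2
        return 0.5 * (breaks[:-1] + breaks[1:])

    def stratum_classes(self, stratum: int) -> tuple[int, int]:
        return divmod(int(stratum), self.k)

    def stratum_center(self, stratum: int) -> tuple[float, float]:
        i, j = self.stratum_classes(stratum)
        return (
            float(self.class_centers(0)[i]),
            float(self.class_centers(1)[j]),
        )


@dataclass
class SampleSites:
    """Sampled site table plus (optionally) the community at each site.

    ``table`` columns: site_id, row, col, stratum, env1, env2.
    ``communities[i]`` is the set of species present at table row ``i``.
    """

    table: pd.DataFrame
    communities: list[frozenset] | None = None

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSites":
        return cls(pd.read_csv(path))


@dataclass
class OccurrenceGrid:
    """Presence/absence of each species on the grid: shape
    ``(n_species, rows, cols)`` booleans."""

    species: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 3 or self.presence.shape[0] != len(self.species):
            raise ValueError("presence must be (n_species, rows, cols)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape[1:]

    def occupancy(self) -> np.ndarray:
        """Per-cell species count."""
        return self.presence.sum(axis=0)

    def community_at(self, row: int, col: int) -> frozenset:
        present = self.presence[:, row, col]
        return frozenset(s for s, p in zip(self.species, present) if p)

    def communities_at(self, rows: Sequence[int], cols: Sequence[int]) -> list[frozenset]:
        return [self.community_at(r, c) for r, c in zip(rows, cols)]

    def collapse(self, mapping: dict[str, str]) -> "OccurrenceGrid":
        """OR species layers that map to the same collapsed label (used
        after tree truncation)."""
        groups: dict[str, list[int]] = {}
        for i, sp in enumerate(self.species):
            groups.setdefault(mapping.get(sp, sp), []).append(i)
        labels = sorted(groups)
        merged = np.stack(
            [self.presence[groups[lbl]].any(axis=0) for lbl in labels]
        )
        return OccurrenceGrid(labels, merged)

    def to_csv(self, path) -> None:
        rows, cols = self.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        data = {"row": rr.ravel(), "col": cc.ravel()}
        for i, sp in enumerate(self.species):
            data[sp] = self.presence[i].ravel().astype(int)
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceGrid":
        df = pd.read_csv(path)
        rows = int(df["row"].max()) + 1
        cols = int(df["col"].max()) + 1
        species = [c for c in df.columns if c not in ("row", "col")]
        presence = np.zeros((len(species), rows, cols), dtype=bool)
        r = df["row"].to_numpy()
        c = df["col"].to_numpy()
        for i, sp in enumerate(species):
            presence[i, r, c] = df[sp].to_numpy() > 0
        return cls(species, presence)


# ----------------------------------------------------------------------
# Turc potential evapotranspiration and summer moisture index
# ----------------------------------------------------------------------

def turc_pet(mean_temp_c, solar_rad, days_in_month: int = 30):
    """Monthly Turc potential evapotranspiration (mm/month).

    ``PET = C * T/(T+15) * (Rs + 50)`` with ``C = 0.40`` for 30/31-day
    months and ``C = 0.37`` for February; ``Rs`` in cal cm-2 day-1.
    Temperatures at or below 0 degC evaporate nothing.
    """
    t = np.asarray(mean_temp_c, dtype=float)
    rs = np.asarray(solar_rad, dtype=float)
    if np.any(t <= -15.0):
        raise ValueError("Turc equation is singular at/below -15 degC")
    if np.any(rs < 0):
        raise ValueError("solar radiation must be non-negative")
    coeff = 0.37 if days_in_month in (28, 29) else 0.40
    pet = coeff * (t / (t + 15.0)) * (rs + 50.0)
    pet = np.where(t <= 0.0, 0.0, pet)
    return float(pet) if pet.ndim == 0 else pet


def moisture_index(precip_jja, pet_jja):
    """Mean over the three warmest months of (precipitation - PET), in mm.

    Accepts three scalars or three equally shaped arrays per argument;
    may be negative (drought).
    """
    precip = [np.asarray(p, dtype=float) for p in precip_jja]
    pet = [np.asarray(p, dtype=float) for p in pet_jja]
    if len(precip) != 3 or len(pet) != 3:
        raise ValueError("moisture index needs exactly 3 monthly values each")
    diffs = [p - e for p, e in zip(precip, pet)]
    mi = sum(diffs) / 3.0
    return float(mi) if np.asarray(mi).ndim == 0 else mi


# ----------------------------------------------------------------------
# Stratification and sampling
# ----------------------------------------------------------------------

def _class_index(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    k = breaks.size - 1
    width = breaks[-1] - breaks[0]
    idx = np.floor((values - breaks[0]) / (width / k)).astype(int)
    return np.clip(idx, 0, k - 1)  # right-closed top class


def stratify(env1: EnvRaster, env2: EnvRaster, k: int = 9) -> StratificationLayer:
    """Cross two equal-width classifications of the land cells.

    Each variable is split into ``k`` classes of equal width spanning its
    observed land min-max; combined ids are ``class1 * k + class2``.
    """
    if env1.shape != env2.shape:
        raise ValueError("raster shapes differ")
    if k < 2:
        raise ValueError("k must be >= 2")
    land = env1.land_mask & env2.land_mask
    breaks = []
    for env in (env1, env2):
        vals = env.values[land]
        vals = vals[np.isfinite(vals)]
        lo, hi = float(vals.min()), float(vals.max())
        if not lo < hi:
            raise ValueError("variable is constant over land; zero-width classes")
        breaks.append(np.linspace(lo, hi, k + 1))
    stratum = np.full(env1.shape, -1, dtype=int)
    defined = land & np.isfinite(env1.values) & np.isfinite(env2.values)
    c1 = _class_index(env1.values[defined], breaks[0])
    c2 = _class_index(env2.values[defined], breaks[1])
    stratum[defined] = c1 * k + c2
    return StratificationLayer(stratum, breaks[0], breaks[1], k)


def allocate_samples(
    strata: StratificationLayer,
    env1: EnvRaster,
    env2: EnvRaster,
    occupancy: np.ndarray,
    min_n: int = 1,
    max_n: int = 10,
    seed: int = 0,
    occurrences: OccurrenceGrid | None = None,
) -> SampleSites:
    """Stratified random sampling with per-stratum counts proportional to
    the log of the stratum's eligible-pixel count.

    A cell is eligible if it lies on land, has a stratum and hosts at
    least one species.  Stratum ``s`` with ``n_s`` eligible pixels gets
    ``round(min_n + (max_n - min_n) * (ln n_s - ln n_min)/(ln n_max - ln n_min))``
    sites (clipped to ``[min_n, min(max_n, n_s)]``); the rarest stratum
    gets ``min_n``, the largest ``max_n``.
    """
    if not 1 <= min_n <= max_n:
        raise ValueError("need max_n >= min_n >= 1")
    occupancy = np.asarray(occupancy)
    eligible = (strata.stratum_id >= 0) & (occupancy > 0)
    if not eligible.any():
        raise ValueError("no eligible (occupied, stratified) pixels anywhere")
    ids = strata.stratum_id[eligible]
    uniq, counts = np.unique(ids, return_counts=True)
    n_min, n_max = counts.min(), counts.max()
    rng = np.random.default_rng(seed)
    records = []
    cell_rows, cell_cols = np.nonzero(eligible)
    for s, n_s in zip(uniq, counts):
        if n_min == n_max:
            target = max_n  # degenerate: all strata equal-sized
        else:
            frac = (math.log(n_s) - math.log(n_min)) / (
                math.log(n_max) - math.log(n_min)
            )
            target = int(math.floor(min_n + (max_n - min_n) * frac + 0.5))
        target = max(min_n, min(target, max_n, int(n_s)))
        members = np.flatnonzero(ids == s)
        chosen = rng.choice(members, size=target, replace=False)
        for m in sorted(chosen):
            r, c = int(cell_rows[m]), int(cell_cols[m])
            records.append((r, c, int(s), env1.values[r, c], env2.values[r, c]))
    table = pd.DataFrame(
        records, columns=["row", "col", "stratum", "env1", "env2"]
    )
    table.insert(0, "site_id", np.arange(len(table)))
    communities = None
    if occurrences is not None:
        communities = occurrences.communities_at(table["row"], table["col"])
    return SampleSites(table, communities)


# ----------------------------------------------------------------------
# ESRI ASCII grid I/O (text-only raster format)
# ----------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(raster: EnvRaster, path) -> None:
    rows, cols = raster.shape
    vals = np.where(raster.land_mask & np.isfinite(raster.values),
                    raster.values, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {raster.resolution_km}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        for r in range(rows):
            fh.write(" ".join(f"{v:.10g}" for v in vals[r]) + "\n")


def read_ascii_grid(path) -> EnvRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, value = line.split()
        header[key.lower()] = float(value)
    body = np.loadtxt(lines[6:])
    body = np.atleast_2d(body)
    nodata = header.get("nodata_value", _NODATA)
    mask = body != nodata
    values = np.where(mask, body, np.nan)
    return EnvRaster(values, mask, resolution_km=header.get("cellsize", 15.0))
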