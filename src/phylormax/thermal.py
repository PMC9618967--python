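"""Species thermal habitat from occurrence rasters and a depth-layered ocean.

Each species' characteristic temperature is the median of a depth-layered
mean-annual temperature grid over the species' core distribution — the cells
of its occurrence-probability raster with probability >= 0.9 — read at the
grid depth level closest to the species' median depth (e.g. a species with
median depth 130 m uses the 150 m layer when the levels jump from 100 m to
150 m). Mesothermic species, whose body temperature exceeds ambient, get a
fixed +3.5 degC correction.

Grids are held as :class:`xarray.DataArray` objects; small grids travel as
long-format CSV (``depth_m, lat, lon, temp_c`` and ``lat, lon, prob``).
Missing temperature cells (the real interpolation product has gaps in some
shallow coastal seas) are excluded from the median rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "DEFAULT_DEPTH_LEVELS",
    "MESOTHERM_CORRECTION_C",
    "CORE_THRESHOLD",
    "TemperatureGrid",
    "DistributionMap",
    "NoCoreDistributionError",
    "NoOverlapError",
    "core_distribution",
    "nearest_depth_layer",
    "median_temperature",
    "apply_mesothermy",
    "thermal_summary",
]

#: 27 depth levels spanning 0-2000 m; 100 m and 150 m are adjacent, so a
#: median depth of 130 m maps to the 150 m layer.
DEFAULT_DEPTH_LEVELS: tuple[float, ...] = (
    0, 10, 20, 30, 50, 75, 100, 150, 200, 250, 300, 350, 400, 450, 500,
    600, 700, 800, 900, 1000, 1100, 1200, 1300, 1400, 1500, 1750, 2000,
)

#: fixed temperature increment for mesothermic (regionally endothermic) species
MESOTHERM_CORRECTION_C = 3.5

#: occurrence probability defining a species' core distribution
CORE_THRESHOLD = 0.9


class NoCoreDistributionError(ValueError):
    """No raster cell reaches the core-distribution probability threshold."""


class NoOverlapError(ValueError):
    """All core cells are missing from the temperature layer."""


@dataclass
class TemperatureGrid:
    """Depth-layered temperature field, dims ``(depth, lat, lon)`` in degC."""

    temp: xr.DataArray

    def __post_init__(self) -> None:
        if tuple(self.temp.dims) != ("depth", "lat", "lon"):
            raise ValueError(
                f"expected dims (depth, lat, lon), got {self.temp.dims}"
            )
        depths = self.temp["depth"].to_numpy()
        if np.any(np.diff(depths) <= 0) or np.any(depths < 0):
            raise ValueError("depth levels must be non-negative and strictly "
                             "increasing")

    @property
    def depth_levels(self) -> np.ndarray:
        return self.temp["depth"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        df = self.temp.to_dataframe(name="temp_c").reset_index()
        df = df.rename(columns={"depth": "depth_m"})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TemperatureGrid":
        df = pd.read_csv(path)
        da = (
            df.set_index(["depth_m", "lat", "lon"])["temp_c"]
            .to_xarray()
            .rename({"depth_m": "depth"})
        )
        return cls(da)


@dataclass
class DistributionMap:
    """Occurrence-probability raster, dims ``(lat, lon)``, values in [0, 1]."""

    prob: xr.DataArray
    species: str = ""

    def __post_init__(self) -> None:
        if tuple(self.prob.dims) != ("lat", "lon"):
            raise ValueError(f"expected dims (lat, lon), got {self.prob.dims}")
        vals = self.prob.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("occurrence probabilities must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        df = self.prob.to_dataframe(name="prob").reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, species: str = "") -> "DistributionMap":
        df = pd.read_csv(path)
        da = df.set_index(["lat", "lon"])["prob"].to_xarray()
        return cls(da, species=species)


def core_distribution(
    dist: DistributionMap, threshold: float = CORE_THRESHOLD
) -> xr.DataArray:
    """Boolean mask of the core distribution: ``prob >= threshold``.

    The comparison is inclusive and missing probabilities never qualify.
    Raises :class:`NoCoreDistributionError` (naming the species) if the mask
    is empty.
    """
    mask = (dist.prob >= threshold).fillna(False)
    if int(mask.sum()) == 0:
        raise NoCoreDistributionError(
            f"species {dist.species or '<unnamed>'}: no cell reaches "
            f"occurrence probability {threshold}"
        )
    return mask


def nearest_depth_layer(median_depth: float, depth_levels=None) -> float:
    """Grid depth level closest to the species' median depth.

    Distance ties break toward the shallower level. With the default level
    set, a median depth of 130 m returns the 150 m layer.
    """
    if median_depth < 0 or not np.isfinite(median_depth):
        raise ValueError(f"median depth must be >= 0, got {median_depth}")
    levels = np.asarray(
        DEFAULT_DEPTH_LEVELS if depth_levels is None else depth_levels, float
    )
    if levels.size == 0 or np.any(np.diff(levels) <= 0):
        raise ValueError("depth_levels must be non-empty and sorted ascending")
    dist = np.abs(levels - median_depth)
    # argmin returns the first (shallowest) index among ties
    return float(levels[int(np.argmin(dist))])


def median_temperature(
    grid: TemperatureGrid, layer: float, mask: xr.DataArray
) -> tuple[float, int]:
    """Median temperature over masked cells at one depth layer.

    Missing temperature cells are dropped; the even-count median is the mean
    of the two central values. Returns ``(median_temp, n_cells)`` with
    ``n_cells`` the number of contributing (present) cells.
    """
    levels = grid.depth_levels
    if layer not in levels:
        raise ValueError(f"layer {layer} m is not one of the grid levels")
    field = grid.temp.sel(depth=layer)
    mask_aligned, field_aligned = xr.align(mask, field, join="inner")
    if mask_aligned.sizes != mask.sizes:
        raise ValueError("distribution raster and temperature grid are not "
                         "on the same cell registration")
    vals = field_aligned.where(mask_aligned).to_numpy().ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise NoOverlapError(
            f"no temperature coverage under the core distribution at the "
            f"{layer} m layer"
        )
    return float(np.median(vals)), int(vals.size)


def apply_mesothermy(
    temp: float, is_mesotherm: bool, correction: float = MESOTHERM_CORRECTION_C
) -> float:
    """Add the fixed mesothermy correction for flagged species."""
    if not np.isfinite(temp):
        raise ValueError("temperature must be finite")
    return float(temp + correction) if is_mesotherm else float(temp)


def thermal_summary(
    species_table: pd.DataFrame,
    grid: TemperatureGrid,
    maps: dict,
    *,
    threshold: float = CORE_THRESHOLD,
    correction: float = MESOTHERM_CORRECTION_C,
    depth_levels=None,
) -> tuple[pd.DataFrame, list]:
    """Per-species thermal summaries: core mask -> layer -> median -> correction.

    Parameters
    ----------
    species_table
        Columns ``species, median_depth, mesotherm``.
    grid
        The depth-layered temperature field.
    maps
        ``{species: DistributionMap}`` covering every species in the table.

    Returns
    -------
    (summaries, failures)
        ``summaries`` has one row per successful species with columns
        ``species, depth_layer_used, n_cells, median_temp,
        mesotherm_corrected``; per-species errors are collected in
        ``failures`` as ``(species, message)`` without aborting the batch.
    """
    levels = grid.depth_levels if depth_levels is None else depth_levels
    rows, failures = [], []
    for rec in species_table.itertuples(index=False):
        name = str(rec.species)
        try:
            dist = maps[name]
        except KeyError:
            failures.append((name, "no distribution raster"))
            continue
        try:
            mask = core_distribution(dist, threshold)
            layer = nearest_depth_layer(float(rec.median_depth), levels)
            med, n_cells = median_temperature(grid, layer, mask)
            corrected = apply_mesothermy(med, bool(rec.mesotherm), correction)
            rows.append(
                {
                    "species": name,
                    "depth_layer_used": layer,
                    "n_cells": n_cells,
                    "median_temp": corrected,
                    "mesotherm_corrected": bool(rec.mesotherm),
                }
            )
        except (NoCoreDistributionError, NoOverlapError, ValueError) as exc:
            failures.append((name, str(exc)))
    return pd.DataFrame(rows), failures
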