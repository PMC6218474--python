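"""Overlap statistics between species ranges and footprint maps.

Ranges are rasterized by the cell-center rule: a cell belongs to a species'
range iff its center lies inside the range geometry. From the masked
footprint values we compute the cumulative profile E(v) (fraction of range
cells at or below each footprint value), the extent of range strictly above
a threshold, its change between epochs (optionally clamping per-cell
decreases to "no change"), and the mean footprint within the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grid import Grid
from .hfp_builder import HFP_MAX, NODATA, HFPMap

__all__ = [
    "RangeMask",
    "OverlapProfile",
    "ExtentChange",
    "rasterize_range",
    "cumulative_profile",
    "extent_above",
    "extent_change",
    "mean_hfp",
    "extent_table",
]


@dataclass
class RangeMask:
    """Cells (by center-in-polygon) belonging to one species' range."""

    species_id: str
    grid: Grid
    mask: np.ndarray  # boolean raster

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.grid.validate_array(self.mask, "range mask")

    @property
    def n(self) -> int:
        return int(self.mask.sum())


@dataclass
class OverlapProfile:
    """E(v), v = 0..50: fraction of range cells with footprint <= v."""

    species_id: str
    epoch: int
    cumulative: np.ndarray  # length 51, nondecreasing, ends at 1


@dataclass
class ExtentChange:
    species_id: str
    threshold: int
    extent_1993: float
    extent_2009: float
    delta: float
    clamped: bool


def rasterize_range(
    geometry: shapely.Geometry, grid: Grid, species_id: str = ""
) -> RangeMask:
    """Mask of grid cells whose centers fall inside ``geometry``."""
    if geometry is None or geometry.is_empty:
        raise ValueError(f"empty range geometry for species {species_id!r}")
    x, y = grid.cell_centers()
    mask = shapely.contains_xy(geometry, x.ravel(), y.ravel()).reshape(grid.shape)
    if not mask.any():
        raise ValueError(
            f"range geometry for species {species_id!r} covers no cell center"
        )
    return RangeMask(species_id=species_id, grid=grid, mask=mask)


def _masked_values(mask: RangeMask, hfp: HFPMap) -> np.ndarray:
    mask.grid.require_same(hfp.grid, "range mask and HFP map")
    vals = hfp.values[mask.mask]
    vals = vals[vals != NODATA]
    if vals.size == 0:
        raise ValueError(f"range of species {mask.species_id!r} is all nodata")
    return vals


def _histogram(vals: np.ndarray) -> np.ndarray:
    return np.bincount(vals, minlength=HFP_MAX + 1)


def cumulative_profile(mask: RangeMask, hfp: HFPMap) -> OverlapProfile:
    vals = _masked_values(mask, hfp)
    cum = np.cumsum(_histogram(vals)) / vals.size
    return OverlapProfile(species_id=mask.species_id, epoch=hfp.epoch, cumulative=cum)


def _check_threshold(t: int) -> None:
    if not (0 <= int(t) <= HFP_MAX - 1) or int(t) != t:
        raise ValueError(f"threshold must be an integer in [0, {HFP_MAX - 1}], got {t}")


def extent_above(mask: RangeMask, hfp: HFPMap, t: int) -> float:
    """Fraction of range cells with footprint strictly greater than ``t``."""
    _check_threshold(t)
    vals = _masked_values(mask, hfp)
    return float((vals > t).sum() / vals.size)


def extent_change(
    mask: RangeMask,
    hfp93: HFPMap,
    hfp09: HFPMap,
    t: int,
    clamp: bool = True,
) -> ExtentChange:
    """Change in above-threshold extent between the two epochs.

    With ``clamp``, cells whose footprint decreased are evaluated at their
    1993 value in 2009 (the "no change" rule), so the delta is >= 0.
    """
    _check_threshold(t)
    hfp93.grid.require_same(hfp09.grid, "HFP maps")
    e93 = extent_above(mask, hfp93, t)
    hfp09_eff = hfp09
    if clamp:
        both = (hfp93.values != NODATA) & (hfp09.values != NODATA)
        vals = hfp09.values.copy()
        vals[both] = np.maximum(vals[both], hfp93.values[both])
        hfp09_eff = HFPMap(grid=hfp09.grid, epoch=hfp09.epoch, values=vals)
    e09 = extent_above(mask, hfp09_eff, t)
    return ExtentChange(
        species_id=mask.species_id,
        threshold=int(t),
        extent_1993=e93,
        extent_2009=e09,
        delta=e09 - e93,
        clamped=clamp,
    )


def mean_hfp(mask: RangeMask, hfp: HFPMap) -> float:
    return float(_masked_values(mask, hfp).mean())


def extent_table(
    masks: list[RangeMask],
    hfp93: HFPMap,
    hfp09: HFPMap,
    thresholds: range | list[int] = range(HFP_MAX),
    clamp: bool = True,
):
    """Long-format table of extents/deltas: one row per (species, threshold).

    Computed from the two per-epoch histograms per species, so the cost is
    independent of the number of thresholds.
    """
    if clamp:
        both = (hfp93.values != NODATA) & (hfp09.values != NODATA)
        eff = hfp09.values.copy()
        eff[both] = np.maximum(eff[both], hfp93.values[both])
    else:
        eff = hfp09.values
    rows = []
    for mask in masks:
        v93 = _masked_values(mask, hfp93)
        v09 = eff[mask.mask]
        v09 = v09[v09 != NODATA]
        c93 = np.cumsum(_histogram(v93)) / v93.size
        c09 = np.cumsum(_histogram(v09)) / v09.size
        for t in thresholds:
            e93 = 1.0 - c93[t]
            e09 = 1.0 - c09[t]
            rows.append(
                {
                    "species_id": mask.species_id,
                    "t": int(t),
                    "extent93": e93,
                    "extent09": e09,
                    "delta": e09 - e93,
                }
            )
    return pd.DataFrame(rows)
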