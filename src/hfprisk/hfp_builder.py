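"""Scoring of raw pressure layers and assembly of the cumulative footprint map.

Eight raw pressure layers (built environments, croplands, pastures, human
population density, night-time lights, railways, roads, navigable waterways)
are each standardized onto a 0-10 score scale, summed, rounded to integer and
clamped to [0, 50]. Change between two epochs is summarized as a per-cell
delta raster plus a 51x51 transition-count matrix, optionally treating
decreases as "no change".

Scoring rules
-------------
built        10 where present, else 0
crop         7 where present, else 0
pasture      4 where present, else 0
popdensity   10 above 1000 people/km2; below, ``3.333 * log10(density + 1)``
nightlights  deciles of the strictly positive radiances scored 1-10; unlit 0
railways     8 within 500 m of a railway, 0 elsewhere (no indirect impact)
roads        8 within 500 m; exponential decay from 4 out to 15 km; then 0
waterways    4 adjacent to the water, decaying exponentially out to 15 km

The three land-cover layers are mutually exclusive per cell, which is what
pins the maximum attainable sum at 10 + 10 + 10 + 8 + 8 + 4 = 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, GridMismatchError

LAYER_NAMES = (
    "built",
    "crop",
    "pasture",
    "popdensity",
    "nightlights",
    "railways",
    "roads",
    "waterways",
)

#: land-cover layers that cannot co-occur in one cell
EXCLUSIVE_LAYERS = ("built", "crop", "pasture")

HFP_MAX = 50
NODATA = -1

# population density: continuous log score hitting 10 at ~1000 people/km2
POPDENSITY_LOG_COEF = 3.333
POPDENSITY_CUTOFF = 1000.0

__all__ = [
    "PressureStack",
    "ScoredLayer",
    "DecayParams",
    "HFPMap",
    "ChangeProduct",
    "ROAD_DECAY",
    "WATERWAY_DECAY",
    "standardize_layer",
    "distance_decay_score",
    "build_hfp",
    "hfp_change",
    "LAYER_NAMES",
    "HFP_MAX",
    "NODATA",
]


@dataclass(frozen=True)
class DecayParams:
    """Distance-decay scoring for linear features.

    Cells within ``direct_radius_km`` get ``direct_score``; beyond that the
    score starts at ``indirect_score0`` and decays exponentially, reaching
    ``tail_score`` (a value that rounds to zero) at ``max_dist_km``; cells
    farther than ``max_dist_km`` score 0.
    """

    direct_radius_km: float
    direct_score: float
    indirect_score0: float
    max_dist_km: float
    tail_score: float = 0.25

    def __post_init__(self) -> None:
        if not self.direct_radius_km < self.max_dist_km:
            raise ValueError("direct radius must be smaller than max distance")
        if self.tail_score >= 0.5:
            raise ValueError("tail score must round to zero")

    @property
    def k(self) -> float:
        """Decay rate per km, derived so the score at max_dist is tail_score."""
        return math.log(self.indirect_score0 / self.tail_score) / (
            self.max_dist_km - self.direct_radius_km
        )


#: roads: 8 inside the 500 m direct buffer, indirect decay from 4 out to 15 km
ROAD_DECAY = DecayParams(0.5, 8.0, 4.0, 15.0)
#: waterways: 4 at the bank decaying out to 15 km (no wider direct buffer)
WATERWAY_DECAY = DecayParams(0.0, 4.0, 4.0, 15.0)

RAIL_RADIUS_KM = 0.5
RAIL_SCORE = 8.0


@dataclass
class PressureStack:
    """Eight named raw pressure rasters sharing one grid, for one epoch.

    ``built``/``crop``/``pasture`` are boolean presence rasters;
    ``popdensity`` is people per km2; ``nightlights`` is radiance;
    ``railways``/``roads``/``waterways`` are distance-to-feature rasters (km).
    """

    grid: Grid
    epoch: int
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if name not in LAYER_NAMES:
                raise ValueError(f"unknown pressure layer {name!r}")
            self.grid.validate_array(np.asarray(arr), name)
        self._check_exclusive()

    def _check_exclusive(self) -> None:
        present = [
            np.asarray(self.layers[n], dtype=bool)
            for n in EXCLUSIVE_LAYERS
            if n in self.layers
        ]
        if len(present) > 1 and (sum(p.astype(int) for p in present) > 1).any():
            raise ValueError("built/crop/pasture must be mutually exclusive per cell")

    def require_complete(self) -> None:
        missing = [n for n in LAYER_NAMES if n not in self.layers]
        if missing:
            raise ValueError(f"pressure stack missing layers: {missing}")


@dataclass
class ScoredLayer:
    name: str
    scores: np.ndarray  # float raster in [0, 10]; NaN for nodata


@dataclass
class HFPMap:
    """Integer cumulative-pressure raster, values 0-50, NODATA where masked."""

    grid: Grid
    epoch: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.grid.validate_array(self.values, "HFP map")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("HFP map must be integer-valued")
        valid = self.values != NODATA
        if valid.any() and (
            (self.values[valid] < 0).any() or (self.values[valid] > HFP_MAX).any()
        ):
            raise ValueError("HFP values must lie in [0, 50]")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != NODATA


@dataclass
class ChangeProduct:
    """Per-cell delta and (initial, final) transition counts between epochs."""

    delta: np.ndarray
    matrix: np.ndarray  # (51, 51) counts, rows = initial, cols = final
    clamped: bool


def distance_decay_score(distance_km, params: DecayParams):
    """Score a distance (km, scalar or array) under a distance-decay rule."""
    d = np.asarray(distance_km, dtype=float)
    if (d[np.isfinite(d)] < 0).any():
        raise ValueError("distances must be non-negative")
    indirect = params.indirect_score0 * np.exp(
        -params.k * (d - params.direct_radius_km)
    )
    out = np.where(d <= params.direct_radius_km, params.direct_score, indirect)
    out = np.where(d > params.max_dist_km, 0.0, out)
    if np.isscalar(distance_km):
        return float(out)
    return out


def _score_boolean(raw: np.ndarray, score: float) -> np.ndarray:
    arr = np.asarray(raw)
    if arr.dtype != bool:
        uniq = np.unique(arr[~_nanmask(arr)])
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("land-use layers must be boolean (0/1) rasters")
    out = np.where(arr.astype(bool), score, 0.0)
    return _propagate_nan(arr, out)


def _nanmask(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return np.isnan(arr)
    return np.zeros(arr.shape, dtype=bool)


def _propagate_nan(raw: np.ndarray, scored: np.ndarray) -> np.ndarray:
    mask = _nanmask(np.asarray(raw, dtype=float))
    if mask.any():
        scored = scored.astype(float)
        scored[mask] = np.nan
    return scored


def _score_popdensity(raw: np.ndarray) -> np.ndarray:
    d = np.asarray(raw, dtype=float)
    if (d[~np.isnan(d)] < 0).any():
        raise ValueError("population density must be non-negative")
    with np.errstate(invalid="ignore"):
        logscore = POPDENSITY_LOG_COEF * np.log10(d + 1.0)
        out = np.where(d > POPDENSITY_CUTOFF, 10.0, np.minimum(logscore, 10.0))
    return _propagate_nan(d, out)


def _score_nightlights(raw: np.ndarray) -> np.ndarray:
    """Decile scores 1-10 over strictly positive cells; unlit cells score 0.

    Ties at a decile boundary take the lower decile.
    """
    v = np.asarray(raw, dtype=float)
    out = np.zeros(v.shape, dtype=float)
    lit = np.nan_to_num(v, nan=0.0) > 0
    if lit.any():
        edges = np.quantile(v[lit], np.linspace(0.1, 0.9, 9))
        out[lit] = 1.0 + (v[lit][:, None] > edges[None, :]).sum(axis=1)
    return _propagate_nan(v, out)


def _score_distance(raw: np.ndarray, params: DecayParams) -> np.ndarray:
    d = np.asarray(raw, dtype=float)
    out = distance_decay_score(np.nan_to_num(d, nan=0.0), params)
    return _propagate_nan(d, out)


def _score_rail(raw: np.ndarray) -> np.ndarray:
    d = np.asarray(raw, dtype=float)
    if (d[~np.isnan(d)] < 0).any():
        raise ValueError("distances must be non-negative")
    out = np.where(np.nan_to_num(d, nan=np.inf) <= RAIL_RADIUS_KM, RAIL_SCORE, 0.0)
    return _propagate_nan(d, out)


_SCORERS = {
    "built": lambda raw: _score_boolean(raw, 10.0),
    "crop": lambda raw: _score_boolean(raw, 7.0),
    "pasture": lambda raw: _score_boolean(raw, 4.0),
    "popdensity": _score_popdensity,
    "nightlights": _score_nightlights,
    "railways": _score_rail,
    "roads": lambda raw: _score_distance(raw, ROAD_DECAY),
    "waterways": lambda raw: _score_distance(raw, WATERWAY_DECAY),
}


def standardize_layer(
    layer_name: str,
    raw_layer: np.ndarray,
    grid: Grid,
    decay: DecayParams | None = None,
) -> ScoredLayer:
    """Standardize one raw pressure layer onto the 0-10 score scale.

    ``decay`` overrides the default distance-decay parameters for the
    roads/waterways layers; other layers ignore it.
    """
    if layer_name not in LAYER_NAMES:
        raise ValueError(f"unknown pressure layer {layer_name!r}")
    grid.validate_array(np.asarray(raw_layer), layer_name)
    if decay is not None and layer_name in ("roads", "waterways"):
        scores = _score_distance(np.asarray(raw_layer), decay)
    else:
        scores = _SCORERS[layer_name](raw_layer)
    return ScoredLayer(name=layer_name, scores=scores)


def build_hfp(
    stack: PressureStack, decay: dict[str, DecayParams] | None = None
) -> HFPMap:
    """Sum the eight standardized layers into an integer 0-50 footprint map.

    Rounding is half-up; any cell with nodata (NaN) in any layer is NODATA
    in the output. ``decay`` optionally maps ``roads``/``waterways`` to
    custom :class:`DecayParams`.
    """
    stack.require_complete()
    decay = decay or {}
    total = np.zeros(stack.grid.shape, dtype=float)
    for name in LAYER_NAMES:
        scored = standardize_layer(
            name, stack.layers[name], stack.grid, decay.get(name)
        )
        total = total + scored.scores
    nodata_mask = np.isnan(total)
    total = np.nan_to_num(total, nan=0.0)
    values = np.floor(total + 0.5).astype(np.int64)  # round half-up
    values = np.clip(values, 0, HFP_MAX)
    values[nodata_mask] = NODATA
    return HFPMap(grid=stack.grid, epoch=stack.epoch, values=values)


def hfp_change(map93: HFPMap, map09: HFPMap, clamp_decreases: bool = True) -> ChangeProduct:
    """Delta raster and 51x51 transition matrix between two epoch maps.

    With ``clamp_decreases`` cells where the later map is lower are treated
    as unchanged: the final value is reset to the initial one, so the delta
    is zero and the transition lands on the matrix diagonal.
    """
    map93.grid.require_same(map09.grid, "HFP maps")
    if map93.epoch >= map09.epoch:
        raise GridMismatchError(
            f"epochs out of order: {map93.epoch} !< {map09.epoch}"
        )
    a = map93.values
    b = map09.values.copy()
    valid = (a != NODATA) & (b != NODATA)
    if clamp_decreases:
        dec = valid & (b < a)
        b[dec] = a[dec]
    delta = np.where(valid, (b - a).astype(float), np.nan)
    n = HFP_MAX + 1
    matrix = np.zeros((n, n), dtype=np.int64)
    np.add.at(matrix, (a[valid], b[valid]), 1)
    return ChangeProduct(delta=delta, matrix=matrix, clamped=clamp_decreases)
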