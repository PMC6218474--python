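"""Seeded synthetic inputs with a planted, threshold-dependent risk effect.

Generates everything the rest of the pipeline consumes: eight pressure
layers at two epochs (the second intensified relative to the first),
blob-shaped species ranges, a covariate table, a realm/biome raster pair,
and Red List category histories whose probability of a high-risk transition
is a logistic function of each species' change in above-threshold footprint
extent at a planted threshold ``t_star``. Ground truth (per-species linear
predictor and drawn label) is emitted alongside, so parameter-recovery
checks can compare what was planted with what the analysis recovers.

A single root seed is expanded into named substreams (landscape, species,
labels), so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon

from .biogeography import REALM_CODES
from .grid import Grid, distance_raster
from .hfp_builder import HFPMap, PressureStack, build_hfp
from .range_overlap import RangeMask, extent_change, rasterize_range
from .risk_transitions import (
    HIGH_RISK,
    LOW_RISK,
    CategoryHistory,
    classify_transition,
)

logger = logging.getLogger(__name__)

# substream indices under the root seed
_STREAM_LANDSCAPE = 0
_STREAM_SPECIES = 1
_STREAM_LABELS = 2

TAXON_ORDERS = (
    "Rodentia",
    "Chiroptera",
    "Soricomorpha",
    "Primates",
    "Carnivora",
    "Artiodactyla",
    "Lagomorpha",
    "Didelphimorphia",
)
DIETS = ("carnivore", "omnivore", "herbivore")
HABITAT_CLASSES = (
    "aquatic",
    "artificial",
    "caves",
    "desert",
    "forest",
    "grassland",
    "rocky",
    "savanna",
    "shrubland",
    "generalist",
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimBundle",
    "generate_landscape",
    "generate_species",
    "generate_transitions",
    "simulate",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs for one synthetic world; every draw derives from ``seed``."""

    rows: int = 200
    cols: int = 200
    cell_km: float = 1.0
    seed: int = 0

    # landscape
    n_settlements: int = 8
    n_roads: int = 6
    n_rails: int = 2
    n_rivers: int = 2
    built_fraction: float = 0.03
    crop_fraction: float = 0.12
    pasture_fraction: float = 0.12
    smooth_sigma: float = 5.0
    pop_max: float = 450.0  # keeps epoch-1 density scores below 9
    intensification_rate: float = 0.15
    n_new_roads: int = 0
    landuse_conversion: float = 0.0

    # species
    n_species: int = 300
    range_radius_mean_km: float = 14.0
    range_radius_sigma: float = 0.35
    realm_rows: int = 2
    realm_cols: int = 3
    n_biomes: int = 3

    # planted effect
    t_star: int = 3  # strict threshold ("HFP > t_star") driving risk
    beta: float = 2.0  # effect on the standardized delta-extent
    baseline_high_risk: float = 0.31
    uplisted_within_high: float = 1.0 / 9.0  # threatened-retained : uplisted = 8:1
    downlisted_within_low: float = 1.0 / 61.0  # LC-retained : downlisted = 60:1
    max_label_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_species < 10:
            raise ValueError("n_species must be at least 10")
        if not (0 <= self.t_star <= 49):
            raise ValueError("t_star must lie in [0, 49]")
        for name in (
            "built_fraction",
            "crop_fraction",
            "pasture_fraction",
            "intensification_rate",
            "baseline_high_risk",
            "uplisted_within_high",
            "downlisted_within_low",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def grid(self) -> Grid:
        return Grid(rows=self.rows, cols=self.cols, cell_km=self.cell_km)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticTruth:
    """What was planted: per-species effect inputs and the drawn labels."""

    t_star: int
    beta: float
    table: pd.DataFrame  # species_id, delta_t_star, linear_predictor, p_high, label


@dataclass
class SimBundle:
    """Everything one synthetic world produced, ready for the pipeline."""

    config: SimConfig
    stack93: PressureStack
    stack09: PressureStack
    hfp93: HFPMap
    hfp09: HFPMap
    ranges: dict[str, shapely.Geometry]
    masks: list[RangeMask]
    covariates: pd.DataFrame
    realm_raster: np.ndarray
    biome_raster: np.ndarray
    realm_legend: dict[int, str]
    catalogue: list[CategoryHistory] = field(default_factory=list)
    truth: SyntheticTruth | None = None


def _smooth_field(rng: np.random.Generator, grid: Grid, sigma: float) -> np.ndarray:
    """Standardized spatially autocorrelated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def _random_polyline(rng: np.random.Generator, grid: Grid, n_knots: int = 3) -> LineString:
    """A polyline crossing the grid between two random boundary points."""
    def boundary_point() -> tuple[float, float]:
        side = rng.integers(4)
        u = rng.uniform()
        if side == 0:
            return grid.x0 + u * (grid.x_right - grid.x0), grid.y_top
        if side == 1:
            return grid.x0 + u * (grid.x_right - grid.x0), grid.y_bottom
        if side == 2:
            return grid.x0, grid.y_bottom + u * (grid.y_top - grid.y_bottom)
        return grid.x_right, grid.y_bottom + u * (grid.y_top - grid.y_bottom)

    start, end = boundary_point(), boundary_point()
    mids = [
        (
            rng.uniform(grid.x0, grid.x_right),
            rng.uniform(grid.y_bottom, grid.y_top),
        )
        for _ in range(max(0, n_knots - 2))
    ]
    return LineString([start, *mids, end])


def generate_landscape(config: SimConfig) -> tuple[PressureStack, PressureStack]:
    """Epoch-1 pressure layers and an intensified epoch-2 copy.

    Epoch 2 raises population density (by two score units, up to the cap)
    inside a spatially coherent mask covering ``intensification_rate`` of
    the grid, optionally adds new roads and converts pasture to cropland
    near existing pressure. With rate 0 and no extra knobs the two stacks
    are identical.
    """
    grid = config.grid
    rng = config.rng(_STREAM_LANDSCAPE)

    develop = _smooth_field(rng, grid, config.smooth_sigma)
    landuse = _smooth_field(rng, grid, config.smooth_sigma)

    built = develop > np.quantile(develop, 1.0 - config.built_fraction)
    free = ~built
    crop_cut = np.quantile(landuse[free], 1.0 - config.crop_fraction)
    crop = free & (landuse > crop_cut)
    free = free & ~crop
    pasture_cut = np.quantile(landuse[free], 1.0 - config.pasture_fraction)
    pasture = free & (landuse > pasture_cut)

    z = develop - develop.max()
    pop = config.pop_max * np.exp(1.5 * z) * rng.lognormal(0.0, 0.2, grid.shape)
    pop = np.minimum(pop, config.pop_max)

    lights = np.where(
        develop > np.quantile(develop, 0.7),
        pop * rng.lognormal(0.0, 0.5, grid.shape),
        0.0,
    )

    roads = [_random_polyline(rng, grid) for _ in range(config.n_roads)]
    rails = [_random_polyline(rng, grid) for _ in range(config.n_rails)]
    rivers = [_random_polyline(rng, grid) for _ in range(config.n_rivers)]

    layers93 = {
        "built": built,
        "crop": crop,
        "pasture": pasture,
        "popdensity": pop,
        "nightlights": lights,
        "railways": distance_raster(rails, grid),
        "roads": distance_raster(roads, grid),
        "waterways": distance_raster(rivers, grid),
    }
    stack93 = PressureStack(grid=grid, epoch=1993, layers=layers93)

    layers09 = {k: np.array(v, copy=True) for k, v in layers93.items()}
    if config.intensification_rate > 0:
        bump_field = _smooth_field(rng, grid, config.smooth_sigma)
        bump = bump_field > np.quantile(bump_field, 1.0 - config.intensification_rate)
        # density score is 3.333*log10(d+1): multiplying (d+1) by 10^(2/3.333)
        # raises the score by two units until the cap
        factor = 10.0 ** (2.0 / 3.333)
        d = layers09["popdensity"]
        d[bump] = (d[bump] + 1.0) * factor - 1.0
        if config.landuse_conversion > 0:
            convertible = layers09["pasture"] & bump
            idx = np.flatnonzero(convertible.ravel())
            take = rng.choice(
                idx,
                size=int(config.landuse_conversion * idx.size),
                replace=False,
            )
            flat_p = layers09["pasture"].ravel()
            flat_c = layers09["crop"].ravel()
            flat_p[take] = False
            flat_c[take] = True
    if config.n_new_roads > 0:
        new_roads = roads + [
            _random_polyline(rng, grid) for _ in range(config.n_new_roads)
        ]
        layers09["roads"] = distance_raster(new_roads, grid)
    stack09 = PressureStack(grid=grid, epoch=2009, layers=layers09)
    return stack93, stack09


def _blob_polygon(
    rng: np.random.Generator, cx: float, cy: float, radius: float, n_vertices: int = 36
) -> Polygon:
    """Star-shaped blob: a circle with smooth multiplicative radial noise."""
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    wobble = gaussian_filter(rng.standard_normal(n_vertices), sigma=3, mode="wrap")
    radii = radius * np.exp(0.35 * wobble)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    poly = Polygon(zip(xs, ys))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def generate_species(
    config: SimConfig, grid: Grid | None = None
) -> tuple[dict[str, shapely.Geometry], list[RangeMask], pd.DataFrame, np.ndarray, np.ndarray, dict[int, str]]:
    """Ranges, covariates and the realm/biome rasters.

    Returns ``(ranges, masks, covariates, realm_raster, biome_raster,
    realm_legend)``. Ranges are blob polygons guaranteed to cover at least
    one cell center (bounded retries, then error).
    """
    grid = grid or config.grid
    rng = config.rng(_STREAM_SPECIES)

    ranges: dict[str, shapely.Geometry] = {}
    masks: list[RangeMask] = []
    for i in range(config.n_species):
        sid = f"sp{i:04d}"
        mask = None
        for _attempt in range(20):
            cx = rng.uniform(grid.x0, grid.x_right)
            cy = rng.uniform(grid.y_bottom, grid.y_top)
            radius = rng.lognormal(
                math.log(config.range_radius_mean_km), config.range_radius_sigma
            )
            poly = _blob_polygon(rng, cx, cy, radius)
            try:
                mask = rasterize_range(poly, grid, species_id=sid)
            except ValueError:
                continue
            break
        if mask is None:
            raise RuntimeError(f"could not place a range for {sid} after 20 tries")
        ranges[sid] = poly
        masks.append(mask)

    n = config.n_species
    covariates = pd.DataFrame(
        {
            "species_id": list(ranges),
            "popdensity": rng.lognormal(3.0, 1.0, n),
            "pop_growth": rng.normal(0.15, 0.1, n),
            "travel_time": rng.lognormal(4.0, 0.8, n),
            "taxon_order": rng.choice(TAXON_ORDERS, n),
            "gestation_length": rng.lognormal(4.3, 0.6, n),
            "weaning_age": rng.lognormal(3.5, 0.7, n),
            "body_mass": rng.lognormal(5.5, 2.0, n),
            "diet": rng.choice(DIETS, n),
            "habitat_class": rng.choice(HABITAT_CLASSES, n),
            "ndvi": rng.uniform(0.0, 1.0, n),
            "tree_cover": rng.uniform(0.0, 100.0, n),
            "habitat_prevalence": rng.uniform(0.05, 1.0, n),
        }
    )

    realm_raster = np.zeros(grid.shape, dtype=np.int64)
    legend: dict[int, str] = {}
    row_edges = np.linspace(0, grid.rows, config.realm_rows + 1).astype(int)
    col_edges = np.linspace(0, grid.cols, config.realm_cols + 1).astype(int)
    code = 0
    for i in range(config.realm_rows):
        for j in range(config.realm_cols):
            code += 1
            legend[code] = REALM_CODES[(code - 1) % len(REALM_CODES)]
            realm_raster[
                row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]
            ] = code

    biome_field = _smooth_field(rng, grid, config.smooth_sigma)
    edges = np.quantile(biome_field, np.linspace(0, 1, config.n_biomes + 1)[1:-1])
    biome_raster = 1 + np.searchsorted(edges, biome_field.ravel()).reshape(grid.shape)

    return ranges, masks, covariates, realm_raster, biome_raster, legend


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def generate_transitions(
    config: SimConfig,
    masks: list[RangeMask],
    hfp93: HFPMap,
    hfp09: HFPMap,
) -> tuple[list[CategoryHistory], SyntheticTruth]:
    """Category histories whose high-risk odds follow the planted effect.

    For each species the (clamped) change in extent above ``t_star`` is
    standardized; P(high-risk) = logistic(alpha + beta * z); the drawn label
    is realized as a category pair that classifies back to exactly that
    label. Degenerate one-class draws are resampled a bounded number of
    times.
    """
    rng = config.rng(_STREAM_LABELS)
    deltas = np.array(
        [
            extent_change(m, hfp93, hfp09, config.t_star, clamp=True).delta
            for m in masks
        ]
    )
    sd = deltas.std()
    z = (deltas - deltas.mean()) / sd if sd > 0 else np.zeros_like(deltas)
    alpha = _logit(config.baseline_high_risk)
    eta = alpha + config.beta * z
    p_high = 1.0 / (1.0 + np.exp(-eta))

    labels = None
    for attempt in range(config.max_label_retries):
        draw = rng.uniform(size=len(masks)) < p_high
        if 0 < draw.sum() < len(masks):
            labels = draw
            break
        logger.warning("degenerate one-class label draw, resampling (try %d)", attempt + 1)
    if labels is None:
        raise RuntimeError("labels degenerate after bounded retries")

    catalogue: list[CategoryHistory] = []
    for sid, high in zip((m.species_id for m in masks), labels):
        if high:
            if rng.uniform() < config.uplisted_within_high:
                start = rng.choice(("LC", "NT", "VU", "EN"))
                steps = {"LC": 4, "NT": 3, "VU": 2, "EN": 1}[start]
                ladder = ("LC", "NT", "VU", "EN", "CR")
                end = ladder[ladder.index(start) + int(rng.integers(1, steps + 1))]
            else:
                start = end = rng.choice(("NT", "VU", "EN", "CR"))
        else:
            if rng.uniform() < config.downlisted_within_low:
                start = rng.choice(("NT", "VU", "EN", "CR"))
                ladder = ("LC", "NT", "VU", "EN", "CR")
                end = ladder[int(rng.integers(0, ladder.index(start)))]
            else:
                start = end = "LC"
        catalogue.append(CategoryHistory(species_id=sid, cat_start=start, cat_end=end))

    # round-trip guard: the realized pairs must classify back to the draw
    for rec, high in zip(catalogue, labels):
        assert (classify_transition(rec.cat_start, rec.cat_end) == HIGH_RISK) == bool(
            high
        )

    truth = SyntheticTruth(
        t_star=config.t_star,
        beta=config.beta,
        table=pd.DataFrame(
            {
                "species_id": [m.species_id for m in masks],
                "delta_t_star": deltas,
                "linear_predictor": eta,
                "p_high": p_high,
                "label": np.where(labels, HIGH_RISK, LOW_RISK),
            }
        ),
    )
    return catalogue, truth


def simulate(config: SimConfig) -> SimBundle:
    """Run all three generators and build the two footprint maps."""
    stack93, stack09 = generate_landscape(config)
    hfp93 = build_hfp(stack93)
    hfp09 = build_hfp(stack09)
    ranges, masks, covariates, realm_raster, biome_raster, legend = generate_species(
        config, config.grid
    )
    catalogue, truth = generate_transitions(config, masks, hfp93, hfp09)
    return SimBundle(
        config=config,
        stack93=stack93,
        stack09=stack09,
        hfp93=hfp93,
        hfp09=hfp09,
        ranges=ranges,
        masks=masks,
        covariates=covariates,
        realm_raster=realm_raster,
        biome_raster=biome_raster,
        realm_legend=legend,
        catalogue=catalogue,
        truth=truth,
    )
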