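"""Seeded synthetic landscapes for the corridor pipeline.

Emulates the structure of the real inputs — a lowland-to-highland elevation
gradient, a fragmented forest/agriculture mosaic, biomass correlated with
forest cover, a forest-integrity index, and reserve/KBA/country polygon
tables — on a planar metric grid, so that every downstream stage can be
exercised without any download. The reserve table deliberately contains the
pathological records (duplicates, "proposed" status, marine polygons,
UNESCO-MAB biosphere reserves, unreported areas) that the cleaning rules
must remove.

Everything is a pure function of the configuration, including its seed:
the same :class:`LandscapeConfig` always yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.ops
from scipy import ndimage

from .errors import AlignmentError, ConfigError
from .grid import Raster

__all__ = [
    "LANDCOVER_CLASSES",
    "FOREST",
    "LandscapeConfig",
    "SyntheticLandscape",
    "generate_dem",
    "generate_landcover",
    "generate_biomass",
    "generate_integrity",
    "generate_reserves",
    "generate_kbas",
    "generate_countries",
    "generate_landscape",
]

# Fixed 8-class land-cover legend (integer cell codes). Mirrors the semantics
# of a global land-cover product: one tree-cover class plus open and
# anthropogenic matrix classes.
LANDCOVER_CLASSES: dict[int, str] = {
    1: "forest",
    2: "shrubland",
    3: "grassland",
    4: "cropland",
    5: "built_up",
    6: "bare",
    7: "water",
    8: "wetland",
}
FOREST = 1

# relative frequencies of matrix (non-forest) classes
_MATRIX_CLASSES = np.array([4, 3, 2, 5, 6, 8, 7])
_MATRIX_WEIGHTS = np.array([0.34, 0.24, 0.16, 0.07, 0.05, 0.06, 0.08])

# Integrity index on a 0-10 scale (low <6, medium 6-9.6, high >9.6),
# matching the banding of the global forest-integrity product.
INTEGRITY_SCALE_MAX = 10.0


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a synthetic landscape.

    Defaults describe a 30 km x 30 km tropical mountain front at 100 m
    resolution: a lowland coastal plain rising to a > 2500 m cordillera,
    a little over half forested, with forest carbon centred near the
    regional median (biomass in Mt C per cell).
    """

    grid_rows: int = 300
    grid_cols: int = 300
    cell_size: float = 100.0
    elev_max: float = 3000.0
    n_reserves: int = 40
    lowland_fraction: float = 0.45
    forest_fraction: float = 0.55
    biomass_mean: float = 70.0
    biomass_sd: float = 30.0
    n_countries: int = 3
    n_kbas: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ConfigError(f"grid must be at least 10x10, got "
                              f"{self.grid_rows}x{self.grid_cols}")
        if self.cell_size <= 0:
            raise ConfigError(f"cell_size must be > 0, got {self.cell_size}")
        for name in ("lowland_fraction", "forest_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.elev_max < 0:
            raise ConfigError(f"elev_max must be >= 0, got {self.elev_max}")
        if self.biomass_mean < 0:
            raise ConfigError(f"biomass_mean must be >= 0, got {self.biomass_mean}")
        if self.biomass_sd < 0:
            raise ConfigError(f"biomass_sd must be >= 0, got {self.biomass_sd}")
        if self.n_reserves < 6:
            raise ConfigError(
                "n_reserves must be >= 6: the synthetic reserve table guarantees "
                "a duplicated pair plus proposed/marine/UNESCO-MAB/unreported "
                "records, which needs at least six rows"
            )
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)


@dataclass
class SyntheticLandscape:
    """Bundle of aligned rasters and polygon tables for one synthetic world."""

    dem: Raster
    landcover: Raster
    biomass: Raster
    integrity: Raster
    reserves: pd.DataFrame
    kbas: pd.DataFrame
    countries: pd.DataFrame
    config: LandscapeConfig


def _rng(config: LandscapeConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_dem(config: LandscapeConfig) -> Raster:
    """Smooth elevation field spanning [0, elev_max].

    A west-to-east gradient (lowland plain rising to a cordillera) plus
    Gaussian-filtered white noise, rescaled so the minimum is 0 m and the
    maximum is ``elev_max``. The gradient's ramp exponent is chosen so that
    roughly ``lowland_fraction`` of the profile sits at or below 500 m,
    guaranteeing contiguous lowland and highland regions whenever
    ``elev_max`` clears the highland threshold.
    """
    nr, nc = config.shape
    rng = _rng(config, 1)
    t = np.linspace(0.0, 1.0, nc)
    if config.elev_max > 500 and 0.0 < config.lowland_fraction < 1.0:
        # t**p hits 500/elev_max exactly at t = lowland_fraction
        p = math.log(500.0 / config.elev_max) / math.log(config.lowland_fraction)
    else:
        p = 1.0
    gradient = np.broadcast_to(t**p, (nr, nc))
    noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=4.0)
    noise_sd = noise.std()
    if noise_sd > 0:
        noise = noise / noise_sd
    # clip rather than rescale so the calibrated ramp is preserved: the
    # coastal plain bottoms out at 0, the cordillera tops out at elev_max
    field_ = np.clip(gradient + 0.08 * noise, 0.0, 1.0)
    return Raster(field_ * config.elev_max, cell_size=config.cell_size)


def generate_landcover(dem: Raster, config: LandscapeConfig) -> Raster:
    """Fragmented forest/matrix mosaic with highland forest.

    A smoothed random suitability field, boosted above 1500 m so montane
    forest patches exist, is thresholded at the quantile matching
    ``forest_fraction``. Matrix cells are split among cropland, grassland,
    shrubland, built-up, bare, wetland and water. A two-cell-wide non-forest
    strip is carved across the mid-gradient so the mosaic always contains at
    least one matrix gap that corridors must negotiate.
    """
    if dem.shape != config.shape:
        raise AlignmentError(
            f"DEM shape {dem.shape} does not match config grid {config.shape}"
        )
    nr, nc = config.shape
    rng = _rng(config, 2)
    cover = np.empty((nr, nc), dtype=np.int64)

    if config.forest_fraction >= 1.0:
        cover[:] = FOREST
        return dem.with_data(cover)

    suit = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=3.0)
    sd = suit.std()
    if sd > 0:
        suit = suit / sd
    if config.elev_max > 0:
        highland = np.clip((dem.data - 1500.0) / max(config.elev_max - 1500.0, 1.0), 0, 1)
        suit = suit + 1.0 * highland
    # deterministic jitter breaks ties so the top-k cut is exact
    suit = suit + 1e-9 * rng.random((nr, nc))

    n_forest = int(round(config.forest_fraction * nr * nc))
    forest_mask = np.zeros(nr * nc, dtype=bool)
    if n_forest > 0:
        order = np.argsort(suit.ravel())
        forest_mask[order[-n_forest:]] = True
    forest_mask = forest_mask.reshape(nr, nc)

    matrix_u = rng.random((nr, nc))
    edges = np.cumsum(_MATRIX_WEIGHTS) / _MATRIX_WEIGHTS.sum()
    matrix_class = _MATRIX_CLASSES[np.searchsorted(edges, matrix_u, side="right").clip(0, len(_MATRIX_CLASSES) - 1)]
    cover = np.where(forest_mask, FOREST, matrix_class)

    if config.forest_fraction > 0.0:
        gap_col = nc // 2
        cover[:, gap_col : gap_col + 2] = np.where(
            cover[:, gap_col : gap_col + 2] == FOREST, 4, cover[:, gap_col : gap_col + 2]
        )
    return dem.with_data(cover)


def generate_biomass(landcover: Raster, config: LandscapeConfig) -> Raster:
    """Forest aboveground biomass (Mt C per cell), zero off-forest.

    Forest cells draw from Normal(biomass_mean, biomass_sd) truncated at 0;
    with the defaults a visible share of cells exceeds the 100 Mt C
    conductance-modifier cap, exercising the threshold branch.
    """
    if landcover.shape != config.shape:
        raise AlignmentError(
            f"landcover shape {landcover.shape} does not match config grid {config.shape}"
        )
    rng = _rng(config, 3)
    values = rng.normal(config.biomass_mean, config.biomass_sd, size=config.shape)
    values = np.clip(values, 0.0, None)
    values[landcover.data != FOREST] = 0.0
    return landcover.with_data(values)


def generate_integrity(landcover: Raster, config: LandscapeConfig) -> Raster:
    """Forest-integrity index on a 0-10 scale.

    Forest cells get a smoothed field mostly in the medium/high bands
    (>= 6); matrix cells sit low. Spatially smooth so that integrity
    filtering carves patches rather than speckle.
    """
    if landcover.shape != config.shape:
        raise AlignmentError(
            f"landcover shape {landcover.shape} does not match config grid {config.shape}"
        )
    rng = _rng(config, 4)
    raw = ndimage.gaussian_filter(rng.standard_normal(config.shape), sigma=2.0)
    lo, hi = raw.min(), raw.max()
    unit = (raw - lo) / (hi - lo) if hi > lo else np.full(config.shape, 0.5)
    forest = landcover.data == FOREST
    index = np.where(forest, 3.0 + 7.0 * unit, 3.0 * unit)
    return landcover.with_data(index)


# ---------------------------------------------------------------------------
# polygon tables
# ---------------------------------------------------------------------------

_DESIGNATIONS = ("National Park", "Forest Reserve", "Wildlife Refuge",
                 "Biological Reserve", "Natural Monument")


def _blob(rng: np.random.Generator, cx: float, cy: float, radius: float) -> shapely.Polygon:
    """Convex random blob: hull of points scattered on a ring around (cx, cy)."""
    n = int(rng.integers(8, 13))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = radius * rng.uniform(0.7, 1.3, size=n)
    pts = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
    return shapely.MultiPoint(pts).convex_hull


def _pick_center(rng: np.random.Generator, dem: Raster, lo: float, hi: float) -> tuple[float, float]:
    """Random cell center with elevation in [lo, hi]; falls back to any cell."""
    rows, cols = np.nonzero((dem.data >= lo) & (dem.data <= hi))
    if len(rows) == 0:
        rows, cols = np.nonzero(np.ones(dem.shape, dtype=bool))
    i = int(rng.integers(len(rows)))
    return dem.cell_center(int(rows[i]), int(cols[i]))


def generate_reserves(dem: Raster, config: LandscapeConfig) -> pd.DataFrame:
    """Reserve polygon table with guaranteed pathological records.

    Rows 0-5 are fixed fixtures for the cleaning rules:

    ==  =========================================================
    0   large lowland designated reserve (duplicate source, >5 km2)
    1   byte-identical duplicate of row 0
    2   "proposed" reserve in the uplands (mean elevation > 500 m)
    3   marine reserve straddling the western extent edge
    4   'UNESCO-MAB Biosphere Reserve' designation
    5   reserve with unreported area, small (< 5 km2)
    ==  =========================================================

    Remaining rows are generic designated reserves alternating between
    lowland and mid-elevation centres and between sub-5 km2 and larger
    sizes, so the table always holds reserves on both sides of the 5 km2
    area threshold and of the 500 m mean-elevation boundary.
    """
    rng = _rng(config, 5)
    extent = dem.extent_polygon
    xmin, ymin, xmax, ymax = dem.bounds

    records: list[dict] = []

    def add(geom, status="designated", designation=None, marine=False,
            reported=True) -> None:
        i = len(records)
        geom = geom.intersection(extent) if not marine else geom
        designation = designation or _DESIGNATIONS[i % len(_DESIGNATIONS)]
        records.append(
            {
                "id": 1000 + i,
                "name": f"Reserve {i}",
                "status": status,
                "designation": designation,
                "marine": bool(marine),
                "reported_area": round(geom.area / 1e6, 3) if reported else float("nan"),
                "geometry": geom,
            }
        )

    # 0/1: duplicated pair, large and lowland
    cx, cy = _pick_center(rng, dem, 0, 350)
    big = _blob(rng, cx, cy, 2200.0)
    add(big)
    dup = shapely.Polygon(big.exterior.coords)  # identical geometry, new object
    add(dup)
    # 2: proposed, upland
    cx, cy = _pick_center(rng, dem, 501, float("inf"))
    add(_blob(rng, cx, cy, 1800.0), status="proposed")
    # 3: marine, straddling the western extent edge (ocean outside the frame)
    cy = rng.uniform(ymin + 0.25 * (ymax - ymin), ymax - 0.25 * (ymax - ymin))
    add(_blob(rng, xmin, cy, 2000.0), marine=True)
    # 4: UNESCO-MAB biosphere reserve
    cx, cy = _pick_center(rng, dem, 0, 350)
    add(_blob(rng, cx, cy, 1700.0), designation="UNESCO-MAB Biosphere Reserve")
    # 5: unreported area, small
    cx, cy = _pick_center(rng, dem, 0, 350)
    add(_blob(rng, cx, cy, 700.0), reported=False)

    # generic reserves; lowland centres sampled well below the 500 m cut so
    # a blob climbing the gradient usually still averages lowland
    for j in range(config.n_reserves - 6):
        if j % 3 == 2:
            lo, hi = 501.0, 900.0  # just above the lowland boundary
        else:
            lo, hi = 0.0, 350.0
        cx, cy = _pick_center(rng, dem, lo, hi)
        radius = 800.0 if j % 4 == 3 else float(rng.uniform(1500.0, 2800.0))
        add(_blob(rng, cx, cy, radius))

    return pd.DataFrame.from_records(records)


def generate_kbas(dem: Raster, config: LandscapeConfig) -> pd.DataFrame:
    """Key Biodiversity Area polygons: random convex blobs over the extent."""
    rng = _rng(config, 6)
    extent = dem.extent_polygon
    records = []
    for i in range(config.n_kbas):
        cx, cy = _pick_center(rng, dem, 0.0, float("inf"))
        geom = _blob(rng, cx, cy, float(rng.uniform(1200.0, 3200.0))).intersection(extent)
        records.append({"id": 9000 + i, "name": f"KBA {i}", "geometry": geom})
    return pd.DataFrame.from_records(records)


def generate_countries(dem: Raster, config: LandscapeConfig) -> pd.DataFrame:
    """Country polygons partitioning the extent: Voronoi cells of random seeds."""
    rng = _rng(config, 7)
    extent = dem.extent_polygon
    xmin, ymin, xmax, ymax = dem.bounds
    if config.n_countries == 1:
        return pd.DataFrame.from_records(
            [{"id": 1, "name": "Country 1", "geometry": extent}]
        )
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, config.n_countries), rng.uniform(ymin, ymax, config.n_countries)]
    )
    cells = shapely.ops.voronoi_diagram(shapely.MultiPoint(pts), envelope=extent)
    records = []
    for i, (px, py) in enumerate(pts):
        seed_pt = shapely.Point(px, py)
        cell = next(g for g in cells.geoms if g.covers(seed_pt))
        records.append(
            {"id": i + 1, "name": f"Country {i + 1}", "geometry": cell.intersection(extent)}
        )
    return pd.DataFrame.from_records(records)


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate the full aligned bundle for one configuration."""
    dem = generate_dem(config)
    landcover = generate_landcover(dem, config)
    biomass = generate_biomass(landcover, config)
    integrity = generate_integrity(landcover, config)
    return SyntheticLandscape(
        dem=dem,
        landcover=landcover,
        biomass=biomass,
        integrity=integrity,
        reserves=generate_reserves(dem, config),
        kbas=generate_kbas(dem, config),
        countries=generate_countries(dem, config),
        config=config,
    )
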