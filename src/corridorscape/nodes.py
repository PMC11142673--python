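"""Start and end nodes: reserve cleaning, lowland start-node selection,
highland forest end-patch extraction, and point placement.

Start nodes are lowland protected areas (mean elevation <= 500 m, area
>= 5 km2) represented by one interior point each. End patches are
contiguous (8-connected) montane forest: forest-class cells passing the
integrity cutoff, polygonized, retained when >= 5 km2 with mean elevation
>= 1500 m, protected or not. Larger patches receive extra end points on a
hexagonal lattice so least-cost paths need not travel deep into a big
target patch to terminate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .errors import ConfigError, EmptyZoneError, GeometryError, SchemaError
from .grid import Raster, zone_mask
from .synthetic import FOREST

__all__ = [
    "NodeThresholds",
    "clean_reserves",
    "polygon_mean_elevation",
    "interior_point",
    "identify_start_nodes",
    "extract_end_patches",
    "seed_end_points",
]

log = logging.getLogger(__name__)

_REQUIRED_RESERVE_COLUMNS = ("id", "status", "designation", "marine", "reported_area", "geometry")

#: connected-components structure: patches are contiguous under 8-connectivity
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class NodeThresholds:
    """Selection thresholds for start nodes and end patches.

    The area and elevation defaults are the regional-scale rules the
    corridor design rests on: lowland reserves of at least 5 km2 with mean
    elevation at or below 500 m feed start nodes; montane forest patches of
    at least 5 km2 with mean elevation at or above 1500 m are candidate
    refugia. ``integrity_min`` is the cutoff separating "medium or high"
    forest integrity from low on the product's 0-10 scale (6.0, the lower
    edge of the medium band); ``hex_spacing`` is the end-point lattice pitch
    chosen so a minimum-size (5 km2) patch yields a single point and point
    count grows roughly linearly with area.
    """

    min_start_area: float = 5.0       # km2
    lowland_elev_max: float = 500.0   # m
    min_end_area: float = 5.0         # km2
    highland_elev_min: float = 1500.0  # m
    integrity_min: float = 6.0        # index units, 0-10 scale
    hex_spacing: float = 3000.0       # m

    def __post_init__(self) -> None:
        if self.min_start_area <= 0 or self.min_end_area <= 0:
            raise ConfigError("area thresholds must be > 0")
        if self.highland_elev_min <= self.lowland_elev_max:
            raise ConfigError(
                "highland_elev_min must exceed lowland_elev_max "
                f"({self.highland_elev_min} <= {self.lowland_elev_max})"
            )
        if self.hex_spacing <= 0:
            raise ConfigError("hex_spacing must be > 0")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_reserves(
    reserves: pd.DataFrame, land: shapely.Geometry | None = None
) -> pd.DataFrame:
    """Apply the protected-area database cleaning rules.

    Removes duplicated geometries (first occurrence kept), records with
    "proposed" status, 'UNESCO-MAB Biosphere Reserve' designations, and
    records whose reported area is missing. Marine records are kept but
    clipped to ``land`` — only their land portion participates downstream;
    records left with no land portion are dropped. When no land polygon is
    supplied marine geometries are retained whole, with a warning.

    Idempotent: cleaning an already-clean table is a no-op.
    """
    missing = [c for c in _REQUIRED_RESERVE_COLUMNS if c not in reserves.columns]
    if missing:
        raise SchemaError(f"reserve table is missing required column(s): {missing}")

    out = reserves.copy()
    # geometry-level duplicates: normalized WKB as the identity key
    wkb = out["geometry"].map(lambda g: shapely.normalize(g).wkb)
    out = out.loc[~wkb.duplicated(keep="first")]
    out = out.loc[out["status"].str.lower() != "proposed"]
    out = out.loc[out["designation"] != "UNESCO-MAB Biosphere Reserve"]
    out = out.loc[out["reported_area"].notna()]

    marine = out["marine"].astype(bool)
    if marine.any():
        if land is None:
            log.warning(
                "%d marine reserve(s) retained whole: no land polygon supplied "
                "for clipping", int(marine.sum())
            )
        else:
            clipped = out.loc[marine, "geometry"].map(lambda g: g.intersection(land))
            out.loc[marine, "geometry"] = clipped
            empty = out["geometry"].map(lambda g: g.is_empty or g.area == 0)
            out = out.loc[~empty]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# zonal helpers
# ---------------------------------------------------------------------------

def polygon_mean_elevation(polygon: shapely.Geometry, dem: Raster) -> float:
    """Mean of DEM cells whose centers fall inside the polygon."""
    mask = zone_mask(polygon, dem)
    if not mask.any():
        raise EmptyZoneError("polygon covers no DEM cell centers")
    return float(dem.data[mask].mean())


def _polygon_elev_range(polygon: shapely.Geometry, dem: Raster) -> float:
    mask = zone_mask(polygon, dem)
    if not mask.any():
        raise EmptyZoneError("polygon covers no DEM cell centers")
    vals = dem.data[mask]
    return float(vals.max() - vals.min())


def interior_point(polygon: shapely.Geometry) -> shapely.Point:
    """A representative location strictly inside the polygon.

    Works for non-convex shapes whose centroid falls outside; for
    multi-part geometries the point is placed in the largest part.
    """
    if polygon.is_empty or polygon.area == 0:
        raise GeometryError("cannot place an interior point in an empty or zero-area polygon")
    if isinstance(polygon, shapely.MultiPolygon):
        polygon = max(polygon.geoms, key=lambda g: g.area)
    return polygon.representative_point()


# ---------------------------------------------------------------------------
# start nodes
# ---------------------------------------------------------------------------

def identify_start_nodes(
    reserves_clean: pd.DataFrame,
    dem: Raster,
    thresholds: NodeThresholds = NodeThresholds(),
) -> pd.DataFrame:
    """Select lowland start nodes from the cleaned reserve table.

    Keeps exactly the reserves with geometric area >= ``min_start_area``
    and mean elevation <= ``lowland_elev_max`` (both boundaries inclusive).
    Area comes from the polygon geometry in the working planar system; the
    ``reported_area`` attribute only feeds the cleaning rule. Each retained
    reserve carries one interior representative point. Reserves covering no
    DEM cell center are skipped with a warning (their mean elevation is
    undefined at working resolution).

    Returns a table with columns reserve_id, geometry, point, area_km2,
    mean_elev_m, elev_range_m, protection_pct (100 by construction:
    start nodes are protected areas).
    """
    records = []
    for _, row in reserves_clean.iterrows():
        geom = row["geometry"]
        area_km2 = geom.area / 1e6
        if area_km2 < thresholds.min_start_area:
            continue
        try:
            mean_elev = polygon_mean_elevation(geom, dem)
        except EmptyZoneError:
            log.warning("reserve %s covers no DEM cell center; skipped", row["id"])
            continue
        if mean_elev > thresholds.lowland_elev_max:
            continue
        records.append(
            {
                "reserve_id": row["id"],
                "geometry": geom,
                "point": interior_point(geom),
                "area_km2": area_km2,
                "mean_elev_m": mean_elev,
                "elev_range_m": _polygon_elev_range(geom, dem),
                "protection_pct": 100.0,
            }
        )
    if not records:
        log.warning("no start nodes satisfy the lowland selection rules")
        return pd.DataFrame(
            columns=["reserve_id", "geometry", "point", "area_km2",
                     "mean_elev_m", "elev_range_m", "protection_pct"]
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# end patches
# ---------------------------------------------------------------------------

def _cells_to_polygon(rows: np.ndarray, cols: np.ndarray, raster: Raster) -> shapely.Geometry:
    """Union of the square cells at (rows, cols) — a valid edge-sharing coverage."""
    x0 = raster.x_origin + cols * raster.cell_size
    y1 = raster.y_origin + (raster.nrows - rows) * raster.cell_size
    boxes = shapely.box(x0, y1 - raster.cell_size, x0 + raster.cell_size, y1)
    return shapely.coverage_union_all(boxes)


def extract_end_patches(
    landcover: Raster,
    integrity: Raster,
    dem: Raster,
    biomass: Raster,
    thresholds: NodeThresholds = NodeThresholds(),
    reserves_clean: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Delineate montane forest end patches (candidate refugia).

    Connected components (8-connectivity) of cells that are forest AND pass
    the integrity cutoff, polygonized; a component is retained iff its area
    is >= ``min_end_area`` km2 and its mean elevation >= ``highland_elev_min``.
    Patches are kept whether protected or not; if a cleaned reserve table is
    supplied each patch also carries its percent protection.

    Returns a table with columns patch_id, geometry, point, seed_points,
    area_km2, mean_elev_m, elev_range_m, mean_biomass, protection_pct,
    n_end_points.
    """
    landcover.require_alignment(integrity, ("landcover", "integrity"))
    landcover.require_alignment(dem, ("landcover", "dem"))
    landcover.require_alignment(biomass, ("landcover", "biomass"))

    eligible = (landcover.data == FOREST) & (integrity.data >= thresholds.integrity_min)
    labels, n_comp = ndimage.label(eligible, structure=_EIGHT)
    cell_km2 = (landcover.cell_size / 1000.0) ** 2

    reserve_union = None
    if reserves_clean is not None and len(reserves_clean):
        reserve_union = shapely.union_all(
            [g for g, m in zip(reserves_clean["geometry"], reserves_clean["marine"]) if not m]
        )

    records = []
    patch_id = 0
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == comp)
        area_km2 = len(rows) * cell_km2
        if area_km2 < thresholds.min_end_area:
            continue
        elev = dem.data[rows, cols]
        mean_elev = float(elev.mean())
        if mean_elev < thresholds.highland_elev_min:
            continue
        geom = _cells_to_polygon(rows, cols, landcover)
        point = interior_point(geom)
        seeds = seed_end_points(geom, thresholds.hex_spacing)
        protection = 0.0
        if reserve_union is not None and not reserve_union.is_empty:
            protection = 100.0 * geom.intersection(reserve_union).area / geom.area
        records.append(
            {
                "patch_id": patch_id,
                "geometry": geom,
                "point": point,
                "seed_points": seeds,
                "area_km2": area_km2,
                "mean_elev_m": mean_elev,
                "elev_range_m": float(elev.max() - elev.min()),
                "mean_biomass": float(biomass.data[rows, cols].mean()),
                "protection_pct": protection,
                "n_end_points": len(seeds),
            }
        )
        patch_id += 1
    if not records:
        log.warning("no end patches satisfy the montane forest rules")
        return pd.DataFrame(
            columns=["patch_id", "geometry", "point", "seed_points", "area_km2",
                     "mean_elev_m", "elev_range_m", "mean_biomass",
                     "protection_pct", "n_end_points"]
        )
    return pd.DataFrame.from_records(records)


def seed_end_points(patch: shapely.Geometry, hex_spacing: float) -> list[shapely.Point]:
    """End points for one patch: a hexagonal lattice clipped to the polygon.

    The lattice has pitch ``hex_spacing`` (row spacing spacing*sqrt(3)/2,
    alternate rows offset by spacing/2) and is anchored at the patch's
    lower-left bound, making placement deterministic. A patch too small to
    catch any lattice point gets exactly one point, its interior point, so
    every patch is reachable.
    """
    if hex_spacing <= 0:
        raise ConfigError(f"hex_spacing must be > 0, got {hex_spacing}")
    if patch.is_empty or patch.area == 0:
        raise GeometryError("cannot seed end points in an empty patch")
    xmin, ymin, xmax, ymax = patch.bounds
    dy = hex_spacing * math.sqrt(3.0) / 2.0
    points: list[shapely.Point] = []
    j = 0
    y = ymin
    while y <= ymax:
        x = xmin + (hex_spacing / 2.0 if j % 2 else 0.0)
        while x <= xmax:
            if shapely.contains_xy(patch, x, y):
                points.append(shapely.Point(x, y))
            x += hex_spacing
        y += dy
        j += 1
    if not points:
        points = [interior_point(patch)]
    return points
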