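"""File formats: ASCII-grid rasters, GeoJSON polygon tables, YAML configs.

Rasters use the Esri ASCII grid format (plain text, readable by any GIS);
polygon tables are pandas DataFrames with a shapely ``geometry`` column,
serialized as GeoJSON FeatureCollections. Round trips preserve grid,
extent, nodata and values.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import shapely
import shapely.geometry
import yaml

from .errors import AlignmentError, GeometryError, SchemaError
from .grid import Raster

__all__ = [
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "require_columns",
    "repair_geometry",
    "read_config",
    "write_config",
    "check_aligned",
]

_NODATA_DEFAULT = -9999.0


def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an Esri ASCII grid (.asc)."""
    path = Path(path)
    nodata = raster.nodata if raster.nodata is not None else _NODATA_DEFAULT
    data = np.asarray(raster.data, dtype=float)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {float(raster.x_origin):.17g}\n"
        f"yllcorner {float(raster.y_origin):.17g}\n"
        f"cellsize {float(raster.cell_size):.17g}\n"
        f"NODATA_value {float(nodata):.17g}\n"
    )
    body = np.where(np.isnan(data), nodata, data)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.17g")  # exact float64 round trip
    return path


def read_raster(path: str | Path) -> Raster:
    """Read an Esri ASCII grid. NODATA cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    r = Raster(
        data=data,
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        nodata=nodata,
    )
    if r.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: header claims {header['nrows']}x{header['ncols']} "
                         f"but body has {r.shape}")
    return r


def check_aligned(rasters: dict[str, Raster]) -> None:
    """Raise :class:`AlignmentError` naming the offending pair of inputs."""
    items = list(rasters.items())
    ref_name, ref = items[0]
    for name, r in items[1:]:
        ref.require_alignment(r, names=(ref_name, name))


# ---------------------------------------------------------------------------
# vector tables
# ---------------------------------------------------------------------------

def require_columns(table: pd.DataFrame, columns: Iterable[str], what: str = "table") -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def repair_geometry(geom: shapely.Geometry, feature_id: Any = None):
    """Fix an invalid polygon with a zero-width buffer, else raise.

    Returns (geometry, repaired_flag).
    """
    if geom.is_valid:
        return geom, False
    fixed = geom.buffer(0)
    if fixed.is_valid and not fixed.is_empty:
        return fixed, True
    raise GeometryError(f"unrepairable geometry for feature {feature_id!r}")


def _jsonable(value: Any) -> Any:
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        v = float(value)
        return None if math.isnan(v) else v
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def write_vector(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a polygon/point table as a GeoJSON FeatureCollection."""
    require_columns(table, ["geometry"], "vector table")
    features = []
    for _, row in table.iterrows():
        props = {k: _jsonable(v) for k, v in row.items() if k != "geometry"}
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": shapely.geometry.mapping(row["geometry"]),
            }
        )
    path = Path(path)
    with path.open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_vector(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a DataFrame with a geometry column.

    Invalid geometries are repaired with a zero-width buffer where possible;
    unrepairable features raise :class:`GeometryError` listing their ids.
    """
    path = Path(path)
    with path.open() as fh:
        gj = json.load(fh)
    records = []
    bad: list[Any] = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = shapely.geometry.shape(feat["geometry"])
        props = dict(feat.get("properties") or {})
        fid = props.get("id", i)
        try:
            geom, _ = repair_geometry(geom, fid)
        except GeometryError:
            bad.append(fid)
            continue
        props["geometry"] = geom
        records.append(props)
    if bad:
        raise GeometryError(f"{path}: unrepairable geometries for features {bad}")
    table = pd.DataFrame.from_records(records)
    if required:
        require_columns(table, required, str(path))
    return table


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, Any]:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(config: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
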