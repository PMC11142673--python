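"""Raster grid container and cell-center geometry.

A :class:`Raster` is a 2-D numpy array plus a planar georeference: square
cells of side ``cell_size`` (metres), row 0 at the top (north), with
``(x_origin, y_origin)`` the south-west corner of the grid. All pipeline
rasters live in one planar Cartesian coordinate system with metric units;
nothing here does geodesy, and the pipeline never reprojects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .errors import AlignmentError

__all__ = ["Raster", "zone_mask"]


@dataclass
class Raster:
    """A single-band raster on a planar metric grid.

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the northernmost row.
    cell_size : float
        Cell side length in metres.
    x_origin, y_origin : float
        Coordinates of the south-west (lower-left) corner of the grid.
    nodata : float or None
        Sentinel for missing cells, preserved through file round-trips.
    """

    data: np.ndarray
    cell_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x_origin,
            self.y_origin,
            self.x_origin + self.ncols * self.cell_size,
            self.y_origin + self.nrows * self.cell_size,
        )

    @property
    def extent_polygon(self) -> shapely.Polygon:
        return shapely.box(*self.bounds)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Full grids of x and y cell-center coordinates, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin + (self.nrows - rows - 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def cell_containing(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y).

        Points on a shared cell edge belong to the cell east/south of it;
        points on the outer boundary are clamped inward.
        """
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(self.nrows - 1 - np.floor((y - self.y_origin) / self.cell_size))
        row = min(max(row, 0), self.nrows - 1)
        col = min(max(col, 0), self.ncols - 1)
        return row, col

    # -- alignment ------------------------------------------------------
    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
        )

    def require_alignment(self, other: "Raster", names: tuple[str, str] = ("a", "b")) -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"rasters {names[0]!r} and {names[1]!r} are not on the same grid: "
                f"shape {self.shape} vs {other.shape}, cell {self.cell_size} vs "
                f"{other.cell_size}, origin ({self.x_origin}, {self.y_origin}) vs "
                f"({other.x_origin}, {other.y_origin})"
            )

    def with_data(self, data: np.ndarray, nodata: float | None = None) -> "Raster":
        """A new raster on the same grid carrying different values."""
        return replace(self, data=np.asarray(data), nodata=nodata)


def zone_mask(polygon: shapely.Geometry, raster: Raster) -> np.ndarray:
    """Boolean mask of cells whose centers fall strictly inside ``polygon``.

    This is the zonal-inclusion convention used by every zonal statistic in
    the pipeline: a cell belongs to a zone iff its center passes a
    point-in-polygon test (no area weighting). Restricted to the polygon's
    bounding box for speed; the returned mask covers the full grid.
    """
    mask = np.zeros(raster.shape, dtype=bool)
    if polygon.is_empty:
        return mask
    xmin, ymin, xmax, ymax = polygon.bounds
    # candidate cell index window (rows count from the top)
    c0 = max(int(np.floor((xmin - raster.x_origin) / raster.cell_size)), 0)
    c1 = min(int(np.ceil((xmax - raster.x_origin) / raster.cell_size)), raster.ncols)
    r_lo = (ymin - raster.y_origin) / raster.cell_size
    r_hi = (ymax - raster.y_origin) / raster.cell_size
    r0 = max(int(raster.nrows - np.ceil(r_hi)), 0)
    r1 = min(int(raster.nrows - np.floor(r_lo)), raster.nrows)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xs = raster.x_origin + (cols + 0.5) * raster.cell_size
    ys = raster.y_origin + (raster.nrows - rows - 0.5) * raster.cell_size
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
    mask[r0:r1, c0:c1] = inside
    return mask
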