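"""Structural conductance surface (inverse of resistance).

Each land-cover class maps to a conductance value via a lookup table; the
forest class, which lumps everything from degraded to primary stands, is
additionally modified by standing biomass: the modifier is min(b, 100)/100,
so zero-biomass forest conducts nothing extra and cells at or above
100 Mt C keep the full class value. No topographic or climate-dissimilarity
adjustment is applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConductanceLookupError, RasterDataError, ResamplingError
from .grid import Raster

__all__ = [
    "ConductanceLookup",
    "ConductanceSurface",
    "EXAMPLE_LOOKUP",
    "resample_categorical",
    "biomass_modifier",
    "build_conductance",
]


@dataclass(frozen=True)
class ConductanceLookup:
    """class_code -> conductance, plus which classes are forest (modifier-eligible)."""

    values: dict[int, float]
    forest_classes: frozenset[int] = frozenset({1})

    def __post_init__(self) -> None:
        for code, c in self.values.items():
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"conductance for class {code} must be finite and >= 0, got {c}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConductanceLookup":
        """Read a lookup from CSV with columns class_code, conductance, is_forest."""
        values: dict[int, float] = {}
        forest: set[int] = set()
        with Path(path).open() as fh:
            for row in csv.DictReader(fh):
                code = int(row["class_code"])
                values[code] = float(row["conductance"])
                if str(row.get("is_forest", "0")).strip().lower() in {"1", "true", "yes"}:
                    forest.add(code)
        return cls(values=values, forest_classes=frozenset(forest))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class_code", "conductance", "is_forest"])
            for code in sorted(self.values):
                w.writerow([code, self.values[code], int(code in self.forest_classes)])
        return path


#: Illustrative default lookup for the 8-class synthetic legend — forest
#: highest, open/agricultural matrix intermediate, built-up and open water
#: impassable. These are plausible values for medium-large forest mammals,
#: not estimates for any particular species; real analyses should supply a
#: species-grounded table.
EXAMPLE_LOOKUP = ConductanceLookup(
    values={
        1: 1.00,   # forest (modified by biomass)
        2: 0.60,   # shrubland
        3: 0.45,   # grassland
        4: 0.30,   # cropland
        5: 0.00,   # built-up
        6: 0.20,   # bare
        7: 0.00,   # water
        8: 0.50,   # wetland
    },
    forest_classes=frozenset({1}),
)


@dataclass
class ConductanceSurface:
    """Conductance raster plus a provenance record of how it was built."""

    raster: Raster
    provenance: dict

    @property
    def data(self) -> np.ndarray:
        return self.raster.data


def resample_categorical(landcover: Raster, target_cell: float) -> Raster:
    """Modal (majority) resampling of a categorical raster to a coarser grid.

    ``target_cell`` must be an integer multiple of the input cell size; each
    coarse cell takes the most frequent class among its fine cells, ties
    broken by the lowest class code. The output grid keeps the input origin.
    Trailing fine rows/columns that do not fill a whole coarse cell are
    dropped.
    """
    factor_f = target_cell / landcover.cell_size
    factor = int(round(factor_f))
    if factor < 1 or abs(factor_f - factor) > 1e-9:
        raise ResamplingError(
            f"target cell {target_cell} is not an integer multiple of "
            f"input cell {landcover.cell_size}"
        )
    if factor == 1:
        return landcover
    data = np.asarray(landcover.data, dtype=np.int64)
    nr = (data.shape[0] // factor) * factor
    nc = (data.shape[1] // factor) * factor
    blocks = data[:nr, :nc].reshape(nr // factor, factor, nc // factor, factor)
    codes = np.unique(data)
    # per-block count of each class; argmax over ascending codes = lowest-code tie-break
    counts = np.stack([(blocks == c).sum(axis=(1, 3)) for c in codes])
    out = codes[np.argmax(counts, axis=0)]
    # origin: keep the lower-left corner fixed (rows count from the top, so
    # dropping trailing fine rows raises y_origin by the remainder)
    dropped_rows = data.shape[0] - nr
    return Raster(
        out,
        cell_size=target_cell,
        x_origin=landcover.x_origin,
        y_origin=landcover.y_origin + dropped_rows * landcover.cell_size,
    )


def biomass_modifier(biomass: Raster, cap: float = 100.0) -> Raster:
    """Forest-quality modifier in [0, 1]: min(b, cap)/cap.

    0 marks zero-biomass locations, 1 marks locations at or above the cap
    (default 100 Mt C). Negative biomass anywhere is a data error, reported
    with the offending cell index.
    """
    b = np.asarray(biomass.data, dtype=float)
    neg = np.argwhere(b < 0)
    if len(neg):
        r, c = neg[0]
        raise RasterDataError(
            f"negative biomass at cell (row={r}, col={c}): {b[r, c]} "
            f"({len(neg)} negative cell(s) total)"
        )
    return biomass.with_data(np.minimum(b, cap) / cap)


def build_conductance(
    landcover: Raster,
    lookup: ConductanceLookup,
    modifier: Raster | None = None,
) -> ConductanceSurface:
    """Apply the class lookup, then the biomass modifier on forest classes.

    Non-forest cells take their class conductance unchanged; forest-flagged
    cells take class conductance times the modifier. The provenance record
    notes the lookup and whether the modifier was applied, so it cannot be
    applied twice.
    """
    codes = np.unique(np.asarray(landcover.data, dtype=np.int64))
    missing = [int(c) for c in codes if int(c) not in lookup.values]
    if missing:
        raise ConductanceLookupError(
            f"land-cover class(es) {missing} have no conductance entry"
        )
    if modifier is not None:
        landcover.require_alignment(modifier, ("landcover", "modifier"))

    data = np.asarray(landcover.data, dtype=np.int64)
    out = np.zeros(data.shape, dtype=float)
    for code in codes:
        out[data == code] = lookup.values[int(code)]
    applied = False
    if modifier is not None and lookup.forest_classes:
        forest = np.isin(data, list(lookup.forest_classes))
        out[forest] *= np.asarray(modifier.data, dtype=float)[forest]
        applied = True
    return ConductanceSurface(
        raster=landcover.with_data(out),
        provenance={
            "lookup": dict(lookup.values),
            "forest_classes": sorted(lookup.forest_classes),
            "modifier_applied": applied,
        },
    )
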