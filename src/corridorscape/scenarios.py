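"""Constructed study scenarios.

Two deterministic landscape constructions used for validation and
demonstration:

* :func:`pairing_study_scenario` — a regional-scale study system with
  exactly 475 lowland start reserves and a montane forest zone holding at
  least 5 end points, reproducing the pairing arithmetic of a k = 5
  nearest-end-point design (475 x 5 = 2375 least-cost paths).
* :func:`dominant_corridor_scenario` — a hand-built landscape in which one
  corridor is extreme on every priority-favoring variable (shortest, most
  protected, most biomass, widest elevation spans, biggest start and end,
  most KBAs), used to check that the priority index recovers a designed
  winner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grid import Raster
from .synthetic import FOREST, LandscapeConfig, generate_biomass, generate_dem, \
    generate_integrity, generate_landcover

__all__ = ["pairing_study_scenario", "dominant_corridor_scenario", "StudyScenario"]


@dataclass
class StudyScenario:
    """Aligned rasters plus reserve/KBA/country tables for one constructed study."""

    dem: Raster
    landcover: Raster
    biomass: Raster
    integrity: Raster
    reserves: pd.DataFrame
    kbas: pd.DataFrame
    countries: pd.DataFrame


def _reserve_record(i, geom, status="designated", designation="National Park",
                    marine=False):
    return {
        "id": i, "name": f"Reserve {i}", "status": status,
        "designation": designation, "marine": marine,
        "reported_area": round(geom.area / 1e6, 3), "geometry": geom,
    }


def pairing_study_scenario(seed: int, n_starts: int = 475) -> StudyScenario:
    """A 300x300-cell study system with ``n_starts`` qualifying start reserves.

    Terrain, land cover, biomass and integrity come from the synthetic
    generators under the given seed; the reserve table is a lattice of
    square reserves (2.3 km side, 5.29 km2 each) packed into the lowland
    strip, every one of which passes the 5 km2 / 500 m start-node rules.
    Reserves overlap on purpose — the real protected-area estate is dense
    in the lowlands — which exercises the union-first protection rule.
    """
    cfg = LandscapeConfig(grid_rows=300, grid_cols=300, seed=seed)
    dem = generate_dem(cfg)
    landcover = generate_landcover(dem, cfg)
    biomass = generate_biomass(landcover, cfg)
    integrity = generate_integrity(landcover, cfg)

    side = 2300.0
    # keep the lattice well west of the 500 m contour (13.5 km): terrain
    # noise (~240 m amplitude) must never push a square's mean over 500 m
    xmax_lowland = 9_000.0
    n_cols = 25
    n_rows = int(np.ceil(n_starts / n_cols))
    xs = np.linspace(200.0, xmax_lowland - side, n_cols)
    ys = np.linspace(300.0, 30_000.0 - side - 300.0, n_rows)
    records = []
    i = 0
    for y in ys:
        for x in xs:
            if i >= n_starts:
                break
            records.append(_reserve_record(i, shapely.box(x, y, x + side, y + side)))
            i += 1
    reserves = pd.DataFrame.from_records(records)

    kbas = pd.DataFrame.from_records(
        [{"id": 9000 + j, "name": f"KBA {j}",
          "geometry": shapely.Point(15_000.0, 4_000.0 + 6_000.0 * j).buffer(2_500.0)}
         for j in range(4)]
    )
    countries = pd.DataFrame.from_records(
        [{"id": 1, "name": "Country 1", "geometry": shapely.box(0, 0, 15_000, 30_000)},
         {"id": 2, "name": "Country 2", "geometry": shapely.box(15_000, 0, 30_000, 30_000)}]
    )
    return StudyScenario(dem, landcover, biomass, integrity, reserves, kbas, countries)


def dominant_corridor_scenario() -> StudyScenario:
    """A landscape with one designed-to-win corridor.

    The southern half holds a tall cordillera (up to 3000 m), a large
    protected montane end patch, a chain of reserves and KBAs along the
    obvious routing corridor, and a high-biomass forest band; the start
    reserve there is the largest in the table and sits closest to the
    highlands. The northern half is a low cordillera (1700 m) with a small,
    unprotected, elevationally narrow end patch far from its small start
    reserves. Every priority-favoring variable therefore peaks on the
    southern start's shortest corridor.
    """
    nr = nc = 150
    cell = 100.0
    x = (np.arange(nc) + 0.5) * cell
    y_top = (nr - np.arange(nr) - 0.5) * cell  # y of each row (row 0 = north)
    xx = np.broadcast_to(x, (nr, nc))
    yy = np.broadcast_to(y_top[:, None], (nr, nc))

    # summit height falls from 3000 m (south) to 1700 m (north half)
    south_max = 1700.0 + 1300.0 * np.clip(1.0 - yy / 7500.0, 0.0, 1.0)
    dem = Raster(xx / 15_000.0 * south_max, cell_size=cell)

    landcover = dem.with_data(np.full((nr, nc), FOREST, dtype=np.int64))

    # high-carbon forest band along the southern routing corridor
    biomass_data = np.full((nr, nc), 20.0)
    biomass_data[(yy < 5_000.0)] = 100.0
    biomass = dem.with_data(biomass_data)

    # integrity passes the medium cutoff only inside the two end patches
    integrity_data = np.full((nr, nc), 4.0)
    south_patch = (xx >= 10_000.0) & (xx <= 14_500.0) & (yy <= 4_000.0)
    north_patch = (xx >= 13_500.0) & (yy >= 10_500.0) & (yy <= 14_000.0)
    integrity_data[south_patch | north_patch] = 9.0
    integrity = dem.with_data(integrity_data)

    records = [
        # the designed winner: big lowland reserve close to the south highlands
        _reserve_record(0, shapely.box(0, 0, 2_400, 5_000)),
        # protection chain along the southern route
        _reserve_record(100, shapely.box(2_400, 1_000, 6_500, 4_000)),
        _reserve_record(101, shapely.box(6_500, 1_000, 10_500, 4_000)),
        # half of the southern end patch is protected
        _reserve_record(102, shapely.box(10_000, 0, 12_200, 4_000)),
    ]
    # small, disjoint northern start reserves, far from every end patch
    rid = 1
    for col in range(2):
        x0 = col * 2_500.0
        for row in range(3):
            y0 = 7_200.0 + row * 2_500.0
            records.append(
                _reserve_record(rid, shapely.box(x0, y0, x0 + 2_320, y0 + 2_200))
            )
            rid += 1
    reserves = pd.DataFrame.from_records(records)

    kbas = pd.DataFrame.from_records(
        [{"id": 9000 + j, "name": f"KBA {j}",
          "geometry": shapely.box(3_000.0 + 3_500.0 * j, 500.0,
                                  5_500.0 + 3_500.0 * j, 3_500.0)}
         for j in range(3)]
    )
    countries = pd.DataFrame.from_records(
        [{"id": 1, "name": "Country 1", "geometry": shapely.box(0, 0, 15_000, 15_000)}]
    )
    return StudyScenario(dem, landcover, biomass, integrity, reserves, kbas, countries)
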