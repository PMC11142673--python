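"""Least-cost paths on the conductance lattice.

The conductance raster becomes a weighted lattice graph: nodes are cells,
edges join neighboring cells (8-connectivity by default, 4 available), and
the cost of stepping between neighbors is the step distance divided by the
arithmetic mean of the two cell conductances. Zero-conductance cells are
hard barriers with no incident edges. Each start node is paired with its k
nearest end points by Euclidean distance and routed with one shortest-path
tree per start (Dijkstra), not one per pair.

Among equal-cost paths the one whose predecessors are lexicographically
smallest in (row, col) is returned, so outputs are byte-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from .conductance import ConductanceSurface
from .errors import ConfigError, StatsInputError, UnreachableError
from .grid import Raster

__all__ = [
    "LatticeGraph",
    "CorridorPath",
    "build_graph",
    "k_nearest_end_points",
    "least_cost_path",
    "batch_corridors",
]

log = logging.getLogger(__name__)

_OFFSETS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))

#: when a start/end point lands on an impassable cell it is snapped to the
#: nearest passable cell within this many cells (Chebyshev radius)
SNAP_RADIUS_CELLS = 5


@dataclass
class LatticeGraph:
    """Weighted lattice over the cells of a conductance surface."""

    matrix: csr_matrix            # symmetric, weight = distance / mean conductance
    surface: ConductanceSurface
    connectivity: int             # 4 or 8
    cell_size: float

    @property
    def raster(self) -> Raster:
        return self.surface.raster

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    def node_of(self, row: int, col: int) -> int:
        return row * self.shape[1] + col

    def cell_of(self, node: int) -> tuple[int, int]:
        return divmod(int(node), self.shape[1])


def build_graph(surface: ConductanceSurface, connectivity: int = 8) -> LatticeGraph:
    """Build the lattice graph from a conductance surface.

    Edge weight between passable neighbors i, j is d(i, j) / ((c_i + c_j)/2)
    with d = cell_size for rook moves and cell_size*sqrt(2) for diagonals.
    Cells with zero conductance get no edges at all.
    """
    if connectivity not in (4, 8):
        raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")
    c = np.asarray(surface.data, dtype=float)
    nr, nc = c.shape
    cell = surface.raster.cell_size
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4

    if not (c > 0).any():
        log.warning("conductance surface is entirely impassable; graph has no edges")

    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    node = np.arange(nr * nc).reshape(nr, nc)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = c[r0:r1, c0:c1]
        b = c[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        dist = cell * (math.sqrt(2.0) if dr and dc else 1.0)
        w = dist / ((a[ok] + b[ok]) / 2.0)
        rows_idx.append(node[r0:r1, c0:c1][ok])
        cols_idx.append(node[r0 + dr : r1 + dr, c0 + dc : c1 + dc][ok])
        weights.append(w)

    n = nr * nc
    if rows_idx:
        mat = coo_matrix(
            (np.concatenate(weights), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(n, n),
        ).tocsr()
    else:
        mat = csr_matrix((n, n))
    return LatticeGraph(matrix=mat, surface=surface, connectivity=connectivity, cell_size=cell)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _point_xy(point) -> tuple[float, float]:
    if isinstance(point, shapely.Point):
        return point.x, point.y
    x, y = point
    return float(x), float(y)


def k_nearest_end_points(
    start_point,
    end_points: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """The k nearest end points by Euclidean distance, ties broken by id.

    ``end_points`` needs columns end_point_id and point. When fewer than k
    end points exist all are returned, with a warning — never an error.
    Distances in the result are non-decreasing.
    """
    if len(end_points) == 0:
        raise StatsInputError("no end points available for pairing")
    sx, sy = _point_xy(start_point)
    d = np.hypot(
        np.array([_point_xy(p)[0] for p in end_points["point"]]) - sx,
        np.array([_point_xy(p)[1] for p in end_points["point"]]) - sy,
    )
    out = end_points.copy()
    out["distance_m"] = d
    out = out.sort_values(["distance_m", "end_point_id"], kind="mergesort")
    if len(out) < k:
        log.warning("only %d end point(s) available, fewer than k=%d", len(out), k)
    return out.head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# shortest paths
# ---------------------------------------------------------------------------

@dataclass
class CorridorPath:
    """One least-cost path from a start node to an end point."""

    start_id: int
    end_point_id: int
    vertices: np.ndarray          # (n, 2) cell-center coordinates, start -> end
    accumulated_cost: float       # resistance-weighted metres
    euclidean_length: float       # straight-line metres between endpoints

    @property
    def linestring(self) -> shapely.Geometry:
        if len(self.vertices) == 1:
            return shapely.Point(self.vertices[0])
        return shapely.LineString(self.vertices)


def _snap_to_passable(raster: Raster, c: np.ndarray, row: int, col: int) -> tuple[int, int]:
    if c[row, col] > 0:
        return row, col
    nr, nc = c.shape
    best = None
    for radius in range(1, SNAP_RADIUS_CELLS + 1):
        r0, r1 = max(0, row - radius), min(nr, row + radius + 1)
        c0, c1 = max(0, col - radius), min(nc, col + radius + 1)
        rows, cols = np.nonzero(c[r0:r1, c0:c1] > 0)
        if len(rows):
            d2 = (rows + r0 - row) ** 2 + (cols + c0 - col) ** 2
            i = int(np.lexsort((cols, rows, d2))[0])
            best = (int(rows[i] + r0), int(cols[i] + c0))
            break
    if best is None:
        raise UnreachableError(
            f"cell ({row}, {col}) is impassable and no passable cell lies within "
            f"{SNAP_RADIUS_CELLS} cells"
        )
    return best


def _node_for_point(graph: LatticeGraph, point) -> int:
    x, y = _point_xy(point)
    row, col = graph.raster.cell_containing(x, y)
    row, col = _snap_to_passable(graph.raster, np.asarray(graph.surface.data, float), row, col)
    return graph.node_of(row, col)


def _backwalk(graph: LatticeGraph, dist: np.ndarray, src: int, dst: int) -> list[int]:
    """Reconstruct the least-cost path from the exact distance field.

    Walking back from the destination, the predecessor of v is any neighbor
    u with dist[u] + w(u, v) == dist[v]; among cost-equal candidates the
    lowest node index — i.e. lexicographically smallest (row, col) — wins.
    """
    mat = graph.matrix
    path = [dst]
    v = dst
    guard = mat.shape[0] + 1
    while v != src:
        lo, hi = mat.indptr[v], mat.indptr[v + 1]
        nbrs = mat.indices[lo:hi]
        w = mat.data[lo:hi]
        resid = np.abs(dist[nbrs] + w - dist[v])
        tol = 1e-9 * max(1.0, abs(dist[v]))
        cand = nbrs[resid <= tol]
        if len(cand) == 0:
            raise UnreachableError(f"path reconstruction failed at node {v}")
        v = int(cand.min())
        path.append(v)
        guard -= 1
        if guard <= 0:
            raise UnreachableError("path reconstruction did not terminate")
    path.reverse()
    return path


def _vertices(graph: LatticeGraph, nodes: list[int]) -> np.ndarray:
    pts = [graph.raster.cell_center(*graph.cell_of(n)) for n in nodes]
    return np.asarray(pts, dtype=float)


def least_cost_path(graph: LatticeGraph, src, dst,
                    start_id: int = -1, end_point_id: int = -1) -> CorridorPath:
    """Exact least-cost path between two locations.

    Locations map to the cells containing them; a location on an impassable
    cell is snapped to the nearest passable cell within a small documented
    radius. Raises :class:`UnreachableError` when no route exists.
    """
    s = _node_for_point(graph, src)
    t = _node_for_point(graph, dst)
    if s == t:
        v = _vertices(graph, [s])
        return CorridorPath(start_id, end_point_id, v, 0.0, 0.0)
    dist = dijkstra(graph.matrix, directed=False, indices=s)
    if not np.isfinite(dist[t]):
        raise UnreachableError(
            f"end point {end_point_id} unreachable from start {start_id} "
            f"(cells {graph.cell_of(s)} -> {graph.cell_of(t)})"
        )
    nodes = _backwalk(graph, dist, s, t)
    verts = _vertices(graph, nodes)
    return CorridorPath(
        start_id,
        end_point_id,
        verts,
        float(dist[t]),
        float(np.hypot(*(verts[-1] - verts[0]))),
    )


def batch_corridors(
    graph: LatticeGraph,
    start_nodes: pd.DataFrame,
    end_points: pd.DataFrame,
    k: int = 5,
) -> tuple[list[CorridorPath], pd.DataFrame]:
    """Route every start node to its k nearest end points.

    One shortest-path tree per start node serves all of its pairings. The
    total pairing count is sum over starts of min(k, number of end points).
    Unreachable pairs are recorded in the returned pairing table with
    status ``"unreachable"`` instead of aborting the batch.

    Returns (paths, pairing_table); the table has columns start_id,
    end_point_id, distance_m, status.
    """
    if len(start_nodes) == 0:
        raise StatsInputError("no start nodes to route from")
    if len(end_points) == 0:
        raise StatsInputError("no end points to route to")

    paths: list[CorridorPath] = []
    pairing_rows: list[dict] = []
    for _, start in start_nodes.iterrows():
        start_id = int(start["reserve_id"])
        pairing = k_nearest_end_points(start["point"], end_points, k=k)
        s = _node_for_point(graph, start["point"])
        dist = dijkstra(graph.matrix, directed=False, indices=s)
        for _, pair in pairing.iterrows():
            end_id = int(pair["end_point_id"])
            t = _node_for_point(graph, pair["point"])
            status = "ok"
            if s == t:
                verts = _vertices(graph, [s])
                paths.append(CorridorPath(start_id, end_id, verts, 0.0, 0.0))
            elif np.isfinite(dist[t]):
                nodes = _backwalk(graph, dist, s, t)
                verts = _vertices(graph, nodes)
                paths.append(
                    CorridorPath(
                        start_id, end_id, verts, float(dist[t]),
                        float(np.hypot(*(verts[-1] - verts[0]))),
                    )
                )
            else:
                status = "unreachable"
                log.warning("end point %d unreachable from start %d", end_id, start_id)
            pairing_rows.append(
                {
                    "start_id": start_id,
                    "end_point_id": end_id,
                    "distance_m": float(pair["distance_m"]),
                    "status": status,
                }
            )
    return paths, pd.DataFrame.from_records(pairing_rows)
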