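"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive — array-scan Dijkstra, exhaustive
path enumeration, cell-by-cell zonal loops, hand-rolled Holm — so that the
production implementations are checked against code that shares none of
their machinery.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import shapely


def naive_dijkstra_cost(cond: np.ndarray, cell: float, src: tuple[int, int],
                        dst: tuple[int, int], connectivity: int = 8) -> float:
    """Array-scan Dijkstra over a conductance grid; returns the path cost.

    Edge weight = distance / mean conductance; zero-conductance cells have
    no edges. Returns inf when unreachable.
    """
    nr, nc = cond.shape
    offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    dist = np.full((nr, nc), np.inf)
    done = np.zeros((nr, nc), dtype=bool)
    if cond[src] <= 0 or cond[dst] <= 0:
        return math.inf
    dist[src] = 0.0
    while True:
        masked = np.where(done, np.inf, dist)
        u = np.unravel_index(np.argmin(masked), masked.shape)
        if not np.isfinite(masked[u]):
            break
        done[u] = True
        if u == dst:
            break
        for dr, dc in offsets:
            v = (u[0] + dr, u[1] + dc)
            if not (0 <= v[0] < nr and 0 <= v[1] < nc):
                continue
            if cond[v] <= 0:
                continue
            d = cell * (math.sqrt(2.0) if dr and dc else 1.0)
            w = d / ((cond[u] + cond[v]) / 2.0)
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
    return float(dist[dst])


def enumerate_paths_cost(cond: np.ndarray, cell: float, src: tuple[int, int],
                         dst: tuple[int, int], connectivity: int = 8) -> float:
    """Minimum cost over ALL simple paths, by exhaustive DFS. Tiny grids only."""
    nr, nc = cond.shape
    offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    if cond[src] <= 0 or cond[dst] <= 0:
        return math.inf
    best = math.inf

    def dfs(u, cost, visited):
        nonlocal best
        if cost >= best:
            return
        if u == dst:
            best = cost
            return
        for dr, dc in offsets:
            v = (u[0] + dr, u[1] + dc)
            if not (0 <= v[0] < nr and 0 <= v[1] < nc) or v in visited:
                continue
            if cond[v] <= 0:
                continue
            d = cell * (math.sqrt(2.0) if dr and dc else 1.0)
            dfs(v, cost + d / ((cond[u] + cond[v]) / 2.0), visited | {v})

    dfs(src, 0.0, {src})
    return best


def zonal_values(polygon: shapely.Geometry, raster) -> np.ndarray:
    """Cell values whose centers lie inside polygon, by an explicit loop."""
    vals = []
    for r in range(raster.nrows):
        for c in range(raster.ncols):
            x, y = raster.cell_center(r, c)
            if shapely.Point(x, y).within(polygon):
                vals.append(raster.data[r, c])
    return np.asarray(vals, dtype=float)


def holm_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Brute-force Holm step-down: sort, multiply by m-i, running max, cap at 1."""
    p_raw = np.asarray(p_raw, dtype=float)
    m = len(p_raw)
    order = np.argsort(p_raw)
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = min((m - i) * p_raw[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


def spearman_midrank(x, y) -> float:
    """Pearson correlation of mid-ranks, computed from first principles."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from explicit rank arithmetic."""
    values = np.concatenate(groups)
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n)
    sv = values[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    rbar = (n + 1) / 2.0
    h = 0.0
    start = 0
    for g in groups:
        gr = ranks[start : start + len(g)]
        h += len(g) * (gr.mean() - rbar) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / correction if correction > 0 else float("nan")


def hex_lattice_count(polygon: shapely.Geometry, spacing: float) -> int:
    """Count of hexagonal-lattice points (anchored at the bounds' lower-left)
    falling inside the polygon — mirrors the documented lattice geometry."""
    xmin, ymin, xmax, ymax = polygon.bounds
    dy = spacing * math.sqrt(3.0) / 2.0
    n = 0
    j = 0
    y = ymin
    while y <= ymax:
        x = xmin + (spacing / 2.0 if j % 2 else 0.0)
        while x <= xmax:
            if shapely.Point(x, y).within(polygon):
                n += 1
            x += spacing
        y += dy
        j += 1
    return n
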