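"""Friction surfaces, accumulated least-cost distance, Euclidean distance.

The accumulated-cost covariate (market access, "Wdist") is the cheapest
travel cost from each cell to its nearest market, found by Dijkstra
shortest paths on the 8-connected lattice.  The cost of stepping between
adjacent cells a and b is the mean of their per-meter friction rates
times the step length (cell resolution for rook moves, resolution * sqrt 2
for diagonals).  Nodata cells are untraversable: they are removed from
the graph, so water/void barriers block routes rather than being crossed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import distance_transform_edt
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .raster import RasterGrid

__all__ = [
    "FrictionSurface",
    "CostSurface",
    "build_friction",
    "accumulated_cost",
    "min_over_sources",
    "euclidean_distance",
]

# default per-meter traversal cost rates (currency/meter) by transport class
DEFAULT_FRICTION_TABLE: dict[str, float] = {
    "class_i_river": 0.0000103,
    "class_ii_river": 0.0000320,
    "class_iii_river": 0.0000534,
    "class_iv_river": 0.0000750,
    "asphalt_road": 0.0001000,
    "dirt_road": 0.0003000,
    "natural_bed_forest": 0.0020000,
}


@dataclass
class FrictionSurface:
    """Per-cell traversal cost rate (currency per meter)."""

    rate: RasterGrid

    def __post_init__(self) -> None:
        vals = self.rate.valid_values()
        if (vals <= 0).any():
            raise ValueError("friction rates must be strictly positive")


@dataclass
class CostSurface:
    """Accumulated least cost to the nearest source cell (currency units)."""

    cost: RasterGrid
    sources: RasterGrid


def build_friction(
    class_raster: RasterGrid, friction_table: Mapping[object, float]
) -> FrictionSurface:
    """Map transport-class codes to per-meter cost rates.

    Every class code present on an unmasked cell must have a table
    entry; an unmapped code raises ``KeyError`` naming it.
    """
    codes = np.unique(class_raster.valid_values())
    rates = np.zeros_like(class_raster.values, dtype=float)
    table = {float(k) if isinstance(k, (int, float)) else k: v
             for k, v in friction_table.items()}
    for code in codes:
        key = float(code)
        if key not in table:
            raise KeyError(f"no friction rate for class code {code!r}")
        rates[class_raster.values == code] = table[key]
    return FrictionSurface(class_raster.like(rates))


def _lattice_graph(friction: FrictionSurface) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse weighted graph over unmasked cells, 8-connected."""
    grid = friction.rate
    mask = grid.mask
    nrows, ncols = grid.shape
    res = grid.resolution_m
    idx = -np.ones(grid.shape, dtype=np.int64)
    idx[mask] = np.arange(mask.sum())
    f = grid.values
    rows, cols, w = [], [], []
    # enumerate each undirected edge once: E, SE, S, SW offsets
    for dr, dc, L in ((0, 1, res), (1, 1, res * np.sqrt(2)),
                      (1, 0, res), (1, -1, res * np.sqrt(2))):
        r0 = slice(0, nrows - dr)
        r1 = slice(dr, nrows)
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = mask[r0, c0] & mask[r1, c1]
        a = idx[r0, c0][ok]
        b = idx[r1, c1][ok]
        cost = 0.5 * (f[r0, c0][ok] + f[r1, c1][ok]) * L
        rows.append(a)
        cols.append(b)
        w.append(cost)
    n = int(mask.sum())
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    w = np.concatenate(w) if w else np.empty(0)
    G = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    return G + G.T, idx


def accumulated_cost(friction: FrictionSurface, sources: RasterGrid) -> CostSurface:
    """Least accumulated cost from every cell to the nearest source cell.

    Unreachable cells (separated from all sources by nodata) get +inf.
    """
    grid = friction.rate
    if sources.shape != grid.shape:
        raise ValueError("source raster shape does not match friction")
    src = (sources.values > 0) & grid.mask
    if not src.any():
        raise ValueError("no source cells")
    G, idx = _lattice_graph(friction)
    src_idx = idx[src]
    d = _csgraph_dijkstra(G, directed=False, indices=src_idx, min_only=True)
    out = np.full(grid.shape, np.inf)
    out[grid.mask] = d
    out[~grid.mask] = 0
    return CostSurface(RasterGrid(out, grid.mask.copy(), grid.resolution_m), sources)


def min_over_sources(costs: Sequence[CostSurface]) -> CostSurface:
    """Element-wise minimum over cost surfaces (nearest of several markets)."""
    if not costs:
        raise ValueError("need at least one cost surface")
    base = costs[0].cost
    acc = base.values.copy()
    src = costs[0].sources.values.astype(bool).copy()
    for c in costs[1:]:
        if c.cost.shape != base.shape:
            raise ValueError("cost surface shapes differ")
        acc = np.minimum(acc, c.cost.values)
        src |= c.sources.values.astype(bool)
    return CostSurface(base.like(acc), base.like(src.astype(float)))


def euclidean_distance(features: RasterGrid) -> RasterGrid:
    """Per-cell Euclidean distance (meters) to the nearest feature cell center.

    Computed with an exact distance transform; masked cells carry no
    value but do not block straight-line distance.
    """
    feat = (features.values > 0) & features.mask
    if not feat.any():
        raise ValueError("empty feature mask")
    d = distance_transform_edt(~feat, sampling=features.resolution_m)
    return features.like(d)
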