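"""Count-matched allocation, cross-tabulation, and fuzzy map comparison.

Goodness of fit for unbalanced binary rasters: the predicted map is
built by thresholding the probability surface at the p* that makes the
predicted count equal the observed count, then compared cell-by-cell
(hits / omissions / commissions) and by Hagen's two-way fuzzy similarity,
which credits near-miss agreement through an exponential distance-decay
kernel w(d) = 2^(-d/2) inside a square window (default 5x5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid

__all__ = [
    "AllocationResult",
    "CrossTab",
    "FuzzyResult",
    "threshold_match",
    "cross_tabulate",
    "fuzzy_two_way",
]


@dataclass
class AllocationResult:
    p_star: float
    predicted_mask: RasterGrid
    observed_count: int
    hits: int | None = None
    omissions: int | None = None
    commissions: int | None = None

    @property
    def hit_fraction(self) -> float | None:
        if self.hits is None or self.observed_count == 0:
            return None
        return self.hits / self.observed_count


@dataclass
class CrossTab:
    hits: int            # predicted 1, actual 1
    omissions: int       # predicted 0, actual 1
    commissions: int     # predicted 1, actual 0
    correct_rejections: int

    @property
    def actual_count(self) -> int:
        return self.hits + self.omissions

    @property
    def hit_fraction(self) -> float:
        n = self.actual_count
        return self.hits / n if n else float("nan")


@dataclass
class FuzzyResult:
    per_cell: np.ndarray
    global_two_way: float
    kernel: int
    population: str


def threshold_match(prob: RasterGrid, observed_count: int,
                    actual: RasterGrid | None = None) -> AllocationResult:
    """Mark the ``observed_count`` most probable cells as changed.

    p* is the probability of the last selected cell, so selecting cells
    with p >= p* reproduces the observed count; ties at p* are broken by
    ascending row-major cell index so the count is exact.
    """
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    mask = prob.mask
    n_valid = int(mask.sum())
    if observed_count > n_valid:
        raise ValueError("observed_count exceeds number of unmasked cells")
    p = prob.values[mask]
    flat_idx = np.flatnonzero(mask.ravel())
    # primary key: probability descending; secondary: row-major index ascending
    order = np.lexsort((flat_idx, -p))
    selected = order[:observed_count]
    pred = np.zeros(prob.shape, dtype=float).ravel()
    pred[flat_idx[selected]] = 1.0
    pred = pred.reshape(prob.shape)
    p_star = float(p[selected[-1]]) if observed_count > 0 else float("inf")
    result = AllocationResult(p_star, prob.like(pred), observed_count)
    if actual is not None:
        ct = cross_tabulate(result.predicted_mask, actual)
        result.hits = ct.hits
        result.omissions = ct.omissions
        result.commissions = ct.commissions
    return result


def cross_tabulate(predicted: RasterGrid, actual: RasterGrid) -> CrossTab:
    """Confusion counts of predicted vs actual change over unmasked cells."""
    if predicted.shape != actual.shape:
        raise ValueError("shape mismatch between predicted and actual")
    mask = predicted.mask & actual.mask
    p = predicted.values[mask] > 0
    a = actual.values[mask] > 0
    return CrossTab(
        hits=int((p & a).sum()),
        omissions=int((~p & a).sum()),
        commissions=int((p & ~a).sum()),
        correct_rejections=int((~p & ~a).sum()),
    )


def _directional_similarity(target: np.ndarray, valid: np.ndarray,
                            kernel: int) -> np.ndarray:
    """max over window cells j with target_j = 1 of 2^(-d/2), per cell."""
    r = kernel // 2
    nrows, ncols = target.shape
    sim = np.zeros(target.shape)
    tgt = target & valid
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            w = 2.0 ** (-np.hypot(dr, dc) / 2.0)
            src_r = slice(max(0, dr), min(nrows, nrows + dr))
            src_c = slice(max(0, dc), min(ncols, ncols + dc))
            dst_r = slice(max(0, -dr), min(nrows, nrows - dr))
            dst_c = slice(max(0, -dc), min(ncols, ncols - dc))
            hit = tgt[src_r, src_c]
            np.maximum(sim[dst_r, dst_c], np.where(hit, w, 0.0),
                       out=sim[dst_r, dst_c])
    return sim


def fuzzy_two_way(map_a: RasterGrid, map_b: RasterGrid, kernel: int = 5,
                  population: str = "a") -> FuzzyResult:
    """Hagen's two-way fuzzy similarity with a 2^(-d/2) decay kernel.

    Each cell's directional similarity to a map is the largest kernel
    weight over that map's changed cells inside the window (0 when the
    window holds none); the per-cell two-way value is the minimum of the
    two directions.  The global statistic averages the per-cell values
    over cells predicted changed in A (``population="a"``) or in either
    map (``population="union"``); it is 1 for identical maps and 0 when
    changed cells are farther apart than the window everywhere.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    if map_a.shape != map_b.shape:
        raise ValueError("shape mismatch between maps")
    if population not in ("a", "union"):
        raise ValueError("population must be 'a' or 'union'")
    valid = map_a.mask & map_b.mask
    a = map_a.values > 0
    b = map_b.values > 0
    sim_to_b = _directional_similarity(b, valid, kernel)
    sim_to_a = _directional_similarity(a, valid, kernel)
    two_way = np.minimum(sim_to_a, sim_to_b)
    two_way[~valid] = 0.0
    pop = (a & valid) if population == "a" else ((a | b) & valid)
    global_val = float(two_way[pop].mean()) if pop.any() else 0.0
    return FuzzyResult(two_way, global_val, kernel, population)
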