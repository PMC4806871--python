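"""Block-region partitions of a raster and region-level spatial weights.

Cells are tiled into square blocks (default 5x5 cells); each surviving
block is a *region*.  Spatial dependence in the hierarchical probit is
defined between regions, not individual cells, which shrinks the weight
matrix from n x n to m x m (e.g. a full 15x15 raster needs a 9x9 region
matrix instead of a 225x225 cell matrix).

Two weight-matrix kinds are provided: rook contiguity on the block
lattice (the four nearest regions, equally weighted) and inverse
distance to the k nearest regions (default 24).  Rows are normalized to
sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .raster import RasterGrid

__all__ = [
    "RegionPartition",
    "RegionWeights",
    "partition_raster",
    "rook_region_weights",
    "inverse_distance_weights",
]


@dataclass
class RegionPartition:
    """Cell-to-region map for a block tiling of a masked raster.

    ``region_id_per_cell`` covers the full lattice with -1 at masked
    cells; labels are 0-based, row-major over the block lattice.
    """

    region_id_per_cell: np.ndarray  # (nrows, ncols) int, -1 = masked
    region_sizes: np.ndarray        # (m,) cells per region
    region_lattice_coords: np.ndarray  # (m, 2) block (row, col) indices
    block: int

    @property
    def m(self) -> int:
        return len(self.region_sizes)

    def cell_region_index(self, mask: np.ndarray) -> np.ndarray:
        """Region label of each unmasked cell, row-major cell order."""
        return self.region_id_per_cell[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": np.arange(self.m),
                "block_row": self.region_lattice_coords[:, 0],
                "block_col": self.region_lattice_coords[:, 1],
                "n_cells": self.region_sizes,
            }
        )


@dataclass
class RegionWeights:
    """Row-normalized sparse m x m region weight matrix."""

    W: sp.csr_matrix
    kind: str  # "rook4" | "invdist24"

    @property
    def m(self) -> int:
        return self.W.shape[0]

    def admissible_interval(self) -> tuple[float, float]:
        """Open interval of admissible spatial-dependence values.

        Bounds are the reciprocals of the extreme real eigenvalues of W
        (1/lambda_min, 1/lambda_max); for a row-stochastic W the upper
        bound is 1.
        """
        m = self.m
        if m <= 600:
            eig = np.linalg.eigvals(self.W.toarray())
        else:
            k = min(m - 2, 16)
            eig = sp.linalg.eigs(self.W.astype(float), k=k, which="LR",
                                 return_eigenvectors=False)
            eig = np.concatenate([
                eig,
                sp.linalg.eigs(self.W.astype(float), k=k, which="SR",
                               return_eigenvectors=False),
            ])
        real = eig.real[np.abs(eig.imag) < 1e-9]
        lam_max = float(real.max())
        lam_min = float(real.min())
        hi = 1.0 / lam_max if lam_max > 0 else np.inf
        lo = 1.0 / lam_min if lam_min < 0 else -np.inf
        return lo, hi


def partition_raster(mask_grid: RasterGrid, block: int = 5) -> RegionPartition:
    """Tile a masked raster into ``block`` x ``block`` regions.

    Cell (r, c) belongs to block (r // block, c // block).  Regions near
    the raster border, or containing nodata, hold fewer than block**2
    cells; blocks with no unmasked cell are dropped.  Labels are stable:
    row-major over surviving block coordinates.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    mask = mask_grid.mask
    if not mask.any():
        raise ValueError("empty partition: all cells are masked")
    nrows, ncols = mask.shape
    br = np.arange(nrows) // block
    bc = np.arange(ncols) // block
    block_row = np.broadcast_to(br[:, None], mask.shape)
    block_col = np.broadcast_to(bc[None, :], mask.shape)
    nbc = ncols // block + (1 if ncols % block else 0)
    flat_block = block_row * nbc + block_col

    counts = np.bincount(flat_block[mask], minlength=flat_block.max() + 1)
    surviving = np.flatnonzero(counts)
    relabel = np.full(len(counts), -1, dtype=int)
    relabel[surviving] = np.arange(len(surviving))

    region_id = np.where(mask, relabel[flat_block], -1)
    coords = np.column_stack([surviving // nbc, surviving % nbc])
    return RegionPartition(region_id, counts[surviving], coords, block)


def rook_region_weights(partition: RegionPartition) -> RegionWeights:
    """Equal weights over the surviving N/S/E/W neighbours on the block lattice."""
    m = partition.m
    if m < 2:
        raise ValueError("no neighbors definable: partition has a single region")
    coords = partition.region_lattice_coords
    index = {tuple(rc): j for j, rc in enumerate(coords)}
    rows, cols = [], []
    for j, (r, c) in enumerate(coords):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            k = index.get((r + dr, c + dc))
            if k is not None:
                rows.append(j)
                cols.append(k)
    W = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m), dtype=float
    )
    return RegionWeights(_row_normalize(W), "rook4")


def inverse_distance_weights(partition: RegionPartition, k: int = 24) -> RegionWeights:
    """Weights proportional to inverse centroid distance to the k nearest regions.

    Distances are Euclidean on the block lattice (unit = one region);
    only ratios matter after row normalization.  Equidistant candidates
    at the k-th place are admitted in ascending label order.
    """
    m = partition.m
    if m < 2:
        raise ValueError("no neighbors definable: partition has a single region")
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = partition.region_lattice_coords.astype(float)
    rows, cols, vals = [], [], []
    for j in range(m):
        d = np.hypot(coords[:, 0] - coords[j, 0], coords[:, 1] - coords[j, 1])
        d[j] = np.inf
        order = np.argsort(d, kind="stable")  # ties -> ascending label
        nearest = order[: min(k, m - 1)]
        rows.extend([j] * len(nearest))
        cols.extend(nearest.tolist())
        vals.extend((1.0 / d[nearest]).tolist())
    W = sp.csr_matrix((vals, (rows, cols)), shape=(m, m), dtype=float)
    return RegionWeights(_row_normalize(W), "invdist24")


def _row_normalize(W: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(W.sum(axis=1)).ravel()
    inv = np.where(sums > 0, 1.0 / np.where(sums > 0, sums, 1.0), 0.0)
    return sp.diags(inv) @ W
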