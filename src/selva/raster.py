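"""Masked raster grids and ESRI ASCII grid I/O.

A :class:`RasterGrid` is a planar lattice of cell values with a constant
cell edge length (``resolution_m``) and a boolean validity mask.  All
grids in an analysis share shape, resolution and mask; geodesy (CRS,
projection) is deliberately out of scope — coordinates are row/column
indices and distances are planar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A 2-D raster with a validity mask and square cells.

    Parameters
    ----------
    values
        2-D array of cell values.  Values under masked cells are
        meaningless and are forced to 0 on construction.
    mask
        Boolean array, ``True`` where the cell is valid (unmasked).
        ``None`` means every cell is valid.
    resolution_m
        Cell edge length in meters.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    resolution_m: float = 900.0
    nodata: float = field(default=DEFAULT_NODATA, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster must be a non-empty 2-D array")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values shape")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")
        # masked cells never carry values
        if (~self.mask).any():
            vals = self.values.copy()
            vals[~self.mask] = 0
            self.values = vals

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        """Values at unmasked cells, row-major order."""
        return self.values[self.mask]

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid with the same mask/resolution but different values."""
        return RasterGrid(values, self.mask.copy(), self.resolution_m, self.nodata)

    def same_lattice(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.resolution_m == other.resolution_m
            and bool((self.mask == other.mask).all())
        )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid in ESRI ASCII format, one header line per key.

    Integer-valued grids are written without a decimal point so the
    round trip is bit exact; floats are written at full repr precision.
    """
    path = Path(path)
    vals = grid.values.astype(float).copy()
    vals[~grid.mask] = grid.nodata
    nrows, ncols = grid.shape
    is_int = np.all(vals == np.round(vals))
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {grid.resolution_m!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        if is_int:
            for row in vals:
                fh.write(" ".join("%d" % v for v in row) + "\n")
        else:
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid.  Raises ``ValueError`` on malformed input."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"missing ESRI ASCII header field {req!r} in {path}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if nrows <= 0 or ncols <= 0:
        raise ValueError("raster has zero extent")
    values = np.array([[float(v) for v in ln.split()] for ln in data_lines])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"data block is {values.shape}, header declares {(nrows, ncols)}"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    mask = values != nodata
    return RasterGrid(values, mask, float(header["cellsize"]), nodata)
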