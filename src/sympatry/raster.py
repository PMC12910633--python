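"""Lightweight categorical/continuous raster grid.

A raster is a row-major 2-D array anchored at a top-left corner with square
cells. Cells are half-open: the cell at (row, col) covers
``[x0 + col*cell, x0 + (col+1)*cell) x (y0 - (row+1)*cell, y0 - row*cell]``
so every planar point maps to exactly one cell. I/O uses the ESRI ASCII grid
format, which any GIS raster stack can ingest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Raster"]


@dataclass
class Raster:
    """A grid of values on a planar coordinate system (metres).

    Parameters
    ----------
    values : ndarray, shape (nrow, ncol)
        Cell values, row 0 at the top (largest y).
    x0, y0 : float
        Planar coordinates of the top-left corner of the grid.
    cell : float
        Cell size in metres (> 0).
    nodata : int or float
        Value used for cells with no data when writing.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float
    nodata: float = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x0,
            self.y0 - self.nrow * self.cell,
            self.x0 + self.ncol * self.cell,
            self.y0,
        )

    def index(self, x, y):
        """Map planar coordinates to (row, col) indices (vectorised).

        Points outside the extent get out-of-range indices; callers decide
        the convention (see :func:`sympatry.habitat.extract_habitat`).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - y) / self.cell).astype(int)
        # top edge belongs to row 0, left edge to col 0 (half-open cells)
        row = np.where((self.y0 - y) == 0.0, 0, row)
        return row, col

    def inside(self, x, y):
        row, col = self.index(x, y)
        return (row >= 0) & (row < self.nrow) & (col >= 0) & (col < self.ncol)

    def value_at(self, x, y, outside=None):
        """Values at planar points; `outside` substituted beyond the extent."""
        row, col = self.index(x, y)
        ok = (row >= 0) & (row < self.nrow) & (col >= 0) & (col < self.ncol)
        rowc = np.clip(row, 0, self.nrow - 1)
        colc = np.clip(col, 0, self.ncol - 1)
        vals = self.values[rowc, colc]
        if outside is not None:
            vals = np.where(ok, vals, outside)
        return vals

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, shape (nrow, ncol)."""
        xs = self.x0 + (np.arange(self.ncol) + 0.5) * self.cell
        ys = self.y0 - (np.arange(self.nrow) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.x0, self.y0, self.cell, self.nodata)

    # ------------------------------------------------------------------ I/O
    def write_ascii(self, path) -> None:
        header = (
            f"ncols {self.ncol}\n"
            f"nrows {self.nrow}\n"
            f"xllcorner {self.x0}\n"
            f"yllcorner {self.y0 - self.nrow * self.cell}\n"
            f"cellsize {self.cell}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            fmt = "%d" if np.issubdtype(self.values.dtype, np.integer) else "%.10g"
            np.savetxt(fh, self.values, fmt=fmt)

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        nrow = int(meta["nrows"])
        cell = meta["cellsize"]
        rast = cls(
            values,
            x0=meta["xllcorner"],
            y0=meta["yllcorner"] + nrow * cell,
            cell=cell,
            nodata=meta.get("nodata_value", -9999),
        )
        if np.allclose(values, np.round(values)):
            rast.values = values.astype(int)
        return rast
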