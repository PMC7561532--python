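"""Minimal single-band raster container with plain-text (Esri ASCII grid) I/O.

Rasters here are small co-registered grids in a projected CRS (meters).
Row 0 of ``values`` is the *northernmost* row, matching the usual
image/grid convention; ``(xllcorner, yllcorner)`` anchor the lower-left
corner of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band regular grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the northern edge.
    cellsize : float
        Cell edge length in meters (> 0).
    xllcorner, yllcorner : float
        Coordinates of the outer lower-left corner of the grid.
    nodata : float
        Sentinel for missing cells in text I/O.
    """

    values: np.ndarray
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid envelope."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x-coordinates of column centers and y-coordinates of row centers."""
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yllcorner + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return xs, ys

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; raises off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xllcorner) / self.cellsize).astype(int)
        row_from_bottom = np.floor((y - self.yllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            i = int(np.argmax(np.atleast_1d(bad)))
            xb = np.atleast_1d(x)[i]
            yb = np.atleast_1d(y)[i]
            raise ValueError(f"point ({xb:.1f}, {yb:.1f}) falls outside the raster")
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell value at each point."""
        row, col = self.index_of(x, y)
        return self.values[row, col]

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-envelope test."""
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def like(self, values: np.ndarray) -> "Raster":
        """New raster sharing this grid's georeferencing."""
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch with template raster")
        return Raster(values, self.cellsize, self.xllcorner, self.yllcorner, self.nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.xllcorner!r}\n"
        f"yllcorner {raster.yllcorner!r}\n"
        f"cellsize {raster.cellsize!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    vals = np.where(np.isnan(raster.values.astype(float)), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return Raster(
        values,
        cellsize=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=nodata,
    )
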