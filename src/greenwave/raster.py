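"""Minimal planar raster container and text I/O.

All rasters in this package live on a planar projected grid in meters.
``values[row, col]`` is stored with row 0 at the *southern* edge, so row
index increases with y.  Pixel centers sit at
``x = x_min + (col + 0.5) * res`` and ``y = y_min + (row + 0.5) * res``.

Rasters are written and read as ESRI ASCII grids (a plain-text format),
which keeps the whole pipeline free of binary dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    """A single-band raster on a square-pixel planar grid."""

    values: np.ndarray  # 2-D, [row, col], row 0 at y_min
    x_min: float
    y_min: float
    res: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.res <= 0:
            raise ValueError("raster resolution must be positive")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_min + self.ncol * self.res

    @property
    def y_max(self) -> float:
        return self.y_min + self.nrow * self.res

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) center-coordinate arrays with the grid's shape."""
        x = self.x_min + (np.arange(self.ncol) + 0.5) * self.res
        y = self.y_min + (np.arange(self.nrow) + 0.5) * self.res
        return np.meshgrid(x, y)

    def index_of(self, x, y):
        """Map map-coordinates to (row, col) indices (arrays allowed).

        Raises ValueError if any point falls outside the raster extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.res).astype(int)
        row = np.floor((y - self.y_min) / self.res).astype(int)
        bad = (col < 0) | (col >= self.ncol) | (row < 0) | (row >= self.nrow)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({x.flat[i]:.1f}, {y.flat[i]:.1f}) outside raster extent "
                f"[{self.x_min}, {self.x_max}] x [{self.y_min}, {self.y_max}]"
            )
        return row, col

    def value_at(self, x, y):
        row, col = self.index_of(x, y)
        return self.values[row, col]

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        path = Path(path)
        vals = np.where(np.isfinite(self.values.astype(float)), self.values, nodata)
        header = (
            f"ncols {self.ncol}\n"
            f"nrows {self.nrow}\n"
            f"xllcorner {self.x_min}\n"
            f"yllcorner {self.y_min}\n"
            f"cellsize {self.res}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            # ESRI ASCII stores the top row first
            np.savetxt(fh, vals[::-1], fmt="%.6g")


def read_ascii(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    return Raster(vals, header["xllcorner"], header["yllcorner"], header["cellsize"])
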