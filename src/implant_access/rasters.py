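"""Minimal aligned-grid raster container with plain-text (ESRI ASCII) I/O.

All rasters in an analysis share one grid: ``cell_size`` meters, origin at
the lower-left corner, row 0 at the top (map convention). Values are floats;
``NaN`` is no-data. Class rasters (land cover, road class) carry small
integer codes plus a ``legend`` mapping code -> class label.

The on-disk format is the ESRI ASCII grid (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by the
values row by row. A legend, when present, is stored next to the grid as
``<name>.legend.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    data: np.ndarray  # 2-D float array, NaN = no-data
    cell_size: float  # meters
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of lower-left corner
    legend: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def point_to_index(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing point (x, y); raises if outside."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.origin[1]) / self.cell_size))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the raster extent")
        return row, col

    def index_to_point(self, row: int, col: int) -> tuple[float, float]:
        """Center coordinates of cell (row, col)."""
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center-coordinate arrays with the raster's shape."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def copy_with(self, data: np.ndarray) -> "Raster":
        return replace(self, data=np.asarray(data, dtype=float))


NODATA = -9999.0


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    data = np.where(np.isnan(raster.data), NODATA, raster.data)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin[0]}\n"
        f"yllcorner {raster.origin[1]}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.6g")
    if raster.legend:
        legend_path = path.with_suffix(path.suffix + ".legend.json")
        legend_path.write_text(json.dumps({str(k): v for k, v in raster.legend.items()}))


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    legend = None
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return Raster(
        data=data,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        legend=legend,
    )
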