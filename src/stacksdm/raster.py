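"""Planar raster grids.

All layers in the package share one geometry convention: planar coordinates
in kilometres, square cells, cell-centre registration, row 0 at the northern
edge, 0-based indices.  Rasters are stored as 2-D float arrays and round-trip
through the ESRI ASCII grid text format (``.asc``), which keeps every
artifact human-readable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid", "morans_i"]

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single georeferenced layer.

    Parameters
    ----------
    data:
        2-D array, ``data[0, :]`` is the northernmost row.
    cell_size:
        Cell edge length in km.
    xmin, ymin:
        Coordinates of the lower-left corner of the grid (km).
    """

    data: np.ndarray
    cell_size: float = 1.0
    xmin: float = 0.0
    ymin: float = 0.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.n_cols * self.cell_size

    @property
    def ymax(self) -> float:
        return self.ymin + self.n_rows * self.cell_size

    @property
    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-centre y coordinates ordered north to south (row order)."""
        return self.ymax - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.xmin, other.xmin)
            and np.isclose(self.ymin, other.ymin)
        )

    def like(self, data: np.ndarray, name: str = "") -> "RasterGrid":
        """New grid with this geometry and different data."""
        if np.shape(data) != self.data.shape:
            raise ValueError("data shape does not match geometry")
        return replace(self, data=np.asarray(data, dtype=float), name=name)

    # -- point <-> cell -----------------------------------------------------
    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing point ``(x, y)``.

        Points on shared cell edges are assigned to the south-east cell
        (floor rule on both axes, with rows growing southward).
        """
        col = int(np.floor((x - self.xmin) / self.cell_size))
        row = int(np.floor((self.ymax - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"point ({x}, {y}) is outside the raster extent "
                f"[{self.xmin}, {self.xmax}] x [{self.ymin}, {self.ymax}]"
            )
        return row, col

    def cell_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xmin) / self.cell_size).astype(int)
        row = np.floor((self.ymax - y) / self.cell_size).astype(int)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(f"point ({x[i]}, {y[i]}) is outside the raster extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_index(x, y)
        return float(self.data[r, c])


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become the NODATA value."""
    data = np.where(np.isnan(grid.data), _NODATA, grid.data)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.xmin!r}\n"
        f"yllcorner {grid.ymin!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii_grid(path, name: str = "") -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    return RasterGrid(
        data=data,
        cell_size=header["cellsize"],
        xmin=header["xllcorner"],
        ymin=header["yllcorner"],
        name=name,
    )


def morans_i(data: np.ndarray) -> float:
    """Lag-1 Moran's I with rook (edge-sharing) neighbours.

    Used to verify the spatial autocorrelation of generated landscapes.
    """
    z = np.asarray(data, dtype=float)
    z = z - z.mean()
    denom = (z**2).sum()
    if denom == 0:
        return 0.0
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    n_pairs = z[:-1, :].size + z[:, :-1].size
    n = z.size
    # each unordered neighbour pair counted once; W = n_pairs
    return float((n / n_pairs) * (num / denom))
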