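"""Planar equal-area grid shared by every spatial layer.

All layers in an analysis (climate, protection, species ranges, countries)
live on one lattice of square cells of equal area (default 21.625 km² per
cell, i.e. ~4.65-km sides).  Coordinates are planar kilometres; in real-data
use the caller is expected to project longitude/latitude into an equal-area
frame before building a :class:`Grid`, while the synthetic world is generated
directly on the plane.

Rows count upward from the grid origin (row 0 is the bottom row), columns
count rightward.  Rasters are plain ``(nrows, ncols)`` numpy arrays indexed
``[row, col]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely


@dataclass(frozen=True)
class Grid:
    """A rectangular lattice of square, equal-area cells.

    Parameters
    ----------
    nrows, ncols:
        Lattice dimensions.
    cell_area_km2:
        Area of each (square) cell; the default matches the 21.625-km²
        analysis resolution.
    x0, y0:
        Planar coordinates (km) of the lower-left corner.
    """

    nrows: int
    ncols: int
    cell_area_km2: float = 21.625
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")

    @property
    def cell_size_km(self) -> float:
        return math.sqrt(self.cell_area_km2)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def width_km(self) -> float:
        return self.ncols * self.cell_size_km

    @property
    def height_km(self) -> float:
        return self.nrows * self.cell_size_km

    @property
    def total_area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2

    # -- point <-> cell ----------------------------------------------------
    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map planar points to (row, col) indices (no bounds check)."""
        cs = self.cell_size_km
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / cs).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / cs).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as two ``(nrows, ncols)`` arrays (X, Y)."""
        cs = self.cell_size_km
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * cs
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * cs
        X, Y = np.meshgrid(xs, ys)
        return X, Y

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        cs = self.cell_size_km
        x = self.x0 + (np.asarray(col) + 0.5) * cs
        y = self.y0 + (np.asarray(row) + 0.5) * cs
        return x, y

    # -- geometry ----------------------------------------------------------
    def cell_box(self, row: int, col: int):
        """Shapely box of one cell."""
        cs = self.cell_size_km
        x = self.x0 + col * cs
        y = self.y0 + row * cs
        return shapely.box(x, y, x + cs, y + cs)

    def cell_boxes(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorized shapely boxes for (rows, cols) arrays."""
        cs = self.cell_size_km
        x = self.x0 + np.asarray(cols) * cs
        y = self.y0 + np.asarray(rows) * cs
        return shapely.box(x, y, x + cs, y + cs)

    def extent_box(self):
        return shapely.box(self.x0, self.y0, self.x0 + self.width_km, self.y0 + self.height_km)

    def refine(self, factor: int) -> "Grid":
        """A grid with each cell subdivided ``factor × factor``."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return Grid(
            nrows=self.nrows * factor,
            ncols=self.ncols * factor,
            cell_area_km2=self.cell_area_km2 / factor**2,
            x0=self.x0,
            y0=self.y0,
        )


def upsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Exact subdivision of a cell mask onto a ``refine(factor)`` grid."""
    return np.kron(np.asarray(mask), np.ones((factor, factor), dtype=mask.dtype))


@dataclass
class ClimateStack:
    """Named climate layers on a shared :class:`Grid`.

    ``layers`` maps layer name to a ``(nrows, ncols)`` float array; ``mask``
    flags valid (land) cells.  Layers that are constant over the valid cells
    are rejected: they carry no niche information and break standardization.
    """

    grid: Grid
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("ClimateStack needs at least one layer")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape does not match grid")
            vals = arr[self.mask]
            if vals.size and np.nanmin(vals) == np.nanmax(vals):
                raise ValueError(f"layer {name!r} is constant over the valid mask")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def values_at(self, cells: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Covariate matrix ``(n_cells, n_layers)`` at (row, col) pairs."""
        cells = np.asarray(cells)
        rows, cols = cells[:, 0], cells[:, 1]
        names = self.names if names is None else names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def valid_cells(self) -> np.ndarray:
        rows, cols = np.nonzero(self.mask)
        return np.column_stack([rows, cols])

    def subset(self, names: list[str]) -> "ClimateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"unknown layers: {missing}")
        return ClimateStack(self.grid, {n: self.layers[n] for n in names}, self.mask)


# -- plain-text raster I/O (ESRI ASCII grid) -------------------------------

def write_ascii_grid(path, array: np.ndarray, grid: Grid, nodata: float = -9999.0) -> None:
    """Write one raster band as an ESRI ASCII grid (text)."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isfinite(arr), arr, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.x0}\n")
        fh.write(f"yllcorner {grid.y0}\n")
        fh.write(f"cellsize {grid.cell_size_km}\n")
        fh.write(f"NODATA_value {nodata}\n")
        # ASCII grids are stored top row first; our row 0 is the bottom row.
        for r in range(grid.nrows - 1, -1, -1):
            fh.write(" ".join(format(float(v), ".17g") for v in out[r]) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        cs = header["cellsize"]
        nodata = header.get("nodata_value", -9999.0)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]  # back to bottom-row-first
    data = np.where(data == nodata, np.nan, data)
    grid = Grid(nrows=nrows, ncols=ncols, cell_area_km2=cs * cs,
                x0=header["xllcorner"], y0=header["yllcorner"])
    return data, grid
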