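"""Minimal gridded-raster containers.

All grids live on an abstract projected, equal-area plane with coordinates in
meters. A :class:`Grid` is a single real- or integer-valued layer; a
:class:`PredictorStack` bundles co-registered named layers sharing one
georeference and one validity mask.

Convention: ``data[row, col]`` with row 0 at the *southern* edge, so
``y = y0 + (row + 0.5) * cell_size`` for cell centers (and analogously for x).
Invalid (nodata) cells are NaN in float layers and masked via ``mask``.

Layers serialize to ESRI ASCII grid files (plain text), the de-facto
text raster interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "PredictorStack", "write_ascii_grid", "read_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Grid:
    """One raster layer on a regular grid (row 0 = south)."""

    data: np.ndarray            # 2D, shape (nrows, ncols)
    origin: tuple[float, float]  # (x, y) of the lower-left corner, meters
    cell_size: float             # meters

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_georef(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (half-open cells)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        nr, nc = self.shape
        if np.any((row < 0) | (row >= nr) | (col < 0) | (col >= nc)):
            raise ValueError("point(s) outside the grid extent")
        return row, col

    def values_at(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return self.data[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each of grid shape."""
        nr, nc = self.shape
        xs = self.origin[0] + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class PredictorStack:
    """Co-registered named layers + shared validity mask.

    ``mask`` is True on valid cells. Layer arrays carry NaN on invalid cells.
    """

    names: list[str]
    data: np.ndarray             # (n_layers, nrows, ncols)
    origin: tuple[float, float]
    cell_size: float
    mask: np.ndarray = field(default=None)  # (nrows, ncols) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (n_layers, nrows, ncols)")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per layer required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        if self.mask is None:
            self.mask = ~np.any(np.isnan(self.data), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape mismatch")
        self.data[:, ~self.mask] = np.nan

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> Grid:
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None
        return Grid(self.data[i], self.origin, self.cell_size)

    def subset(self, names: list[str]) -> "PredictorStack":
        idx = [self.names.index(n) for n in names]
        return PredictorStack(list(names), self.data[idx].copy(),
                              self.origin, self.cell_size, self.mask.copy())

    def grid_template(self) -> Grid:
        return Grid(np.full(self.shape, np.nan), self.origin, self.cell_size)

    def same_georef(self, other: "PredictorStack") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def add_layers(self, other: "PredictorStack") -> "PredictorStack":
        if not self.same_georef(other):
            raise ValueError("stacks are not co-registered")
        return PredictorStack(
            self.names + other.names,
            np.concatenate([self.data, other.data], axis=0),
            self.origin, self.cell_size, self.mask & other.mask,
        )

    # -- extraction ------------------------------------------------------
    def cell_of(self, x, y):
        return self.grid_template().cell_of(x, y)

    def values_at(self, x, y) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at point locations."""
        row, col = self.cell_of(x, y)
        vals = self.data[:, row, col].T
        if np.any(~self.mask[row, col]):
            raise ValueError("point(s) fall on nodata cells")
        return vals

    def valid_rc(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.mask)

    def valid_table(self) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix over valid cells (row-major)."""
        r, c = self.valid_rc()
        return self.data[:, r, c].T

    def valid_xy(self) -> tuple[np.ndarray, np.ndarray]:
        r, c = self.valid_rc()
        x = self.origin[0] + (c + 0.5) * self.cell_size
        y = self.origin[1] + (r + 0.5) * self.cell_size
        return x, y


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a layer as an ESRI ASCII grid (NaN -> NODATA)."""
    nr, nc = grid.shape
    data = np.where(np.isnan(grid.data), _NODATA, grid.data)
    header = (
        f"ncols {nc}\nnrows {nr}\n"
        f"xllcorner {grid.origin[0]}\nyllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI rows run north->south; our row 0 is south
        np.savetxt(fh, data[::-1], fmt="%.10g")


def read_ascii_grid(path) -> Grid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    data[data == hdr["nodata_value"]] = np.nan
    return Grid(data, (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"])
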