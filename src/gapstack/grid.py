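"""Planar raster grid shared by every raster in a run.

All spatial data in gapstack live on a single regular, north-up grid in a
projected coordinate system with meter units.  Row 0 is the northernmost row
(top-left cell origin); cell (row, col) has its center at

    x = xmin + (col + 1/2) * cell_size
    y = ymax - (row + 1/2) * cell_size

Points on the exact right/bottom edge of the extent are assigned to the last
column/row so that a closed extent maps onto the grid without gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    xmin: float
    ymin: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid must have at least one cell, got {self.nrows}x{self.ncols}")

    @classmethod
    def from_extent(cls, extent: tuple[float, float, float, float], cell_size: float) -> "Grid":
        """Build a grid covering ``(xmin, ymin, xmax, ymax)`` with square cells.

        The extent must be an integer number of cells in each direction
        (within 1e-6 of a cell).
        """
        xmin, ymin, xmax, ymax = extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"degenerate extent {extent}")
        if cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {cell_size}")
        ncols = (xmax - xmin) / cell_size
        nrows = (ymax - ymin) / cell_size
        if abs(ncols - round(ncols)) > 1e-6 or abs(nrows - round(nrows)) > 1e-6:
            raise ValueError(f"extent {extent} is not an integer number of {cell_size} m cells")
        return cls(xmin=float(xmin), ymin=float(ymin), cell_size=float(cell_size),
                   nrows=int(round(nrows)), ncols=int(round(ncols)))

    # ------------------------------------------------------------------ geometry
    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell_size

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size ** 2 / 1e6

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center-coordinate arrays of shape (nrows, ncols)."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.ymax - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.xmin + (col + 0.5) * self.cell_size,
                self.ymax - (row + 0.5) * self.cell_size)

    def point_cell(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y); raises if outside the extent."""
        if not (self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax):
            raise ValueError(f"point ({x}, {y}) outside grid extent {self.extent}")
        col = min(int((x - self.xmin) // self.cell_size), self.ncols - 1)
        row = min(int((self.ymax - y) // self.cell_size), self.nrows - 1)
        return row, col

    def points_to_cells(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized ``point_cell`` for an (n, 2) array of x/y coordinates."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"expected (n, 2) points array, got shape {pts.shape}")
        x, y = pts[:, 0], pts[:, 1]
        inside = (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        if not inside.all():
            i = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"point {i} at ({x[i]}, {y[i]}) outside grid extent {self.extent}")
        cols = np.minimum(((x - self.xmin) // self.cell_size).astype(int), self.ncols - 1)
        rows = np.minimum(((self.ymax - y) // self.cell_size).astype(int), self.nrows - 1)
        return rows, cols

    def congruent(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (self.nrows == other.nrows and self.ncols == other.ncols
                and abs(self.xmin - other.xmin) < tol
                and abs(self.ymin - other.ymin) < tol
                and abs(self.cell_size - other.cell_size) < tol)

    def require_congruent(self, other: "Grid") -> None:
        if not self.congruent(other):
            raise ValueError(f"grid mismatch: {self} vs {other}")
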