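"""Planar equal-area raster grid geometry.

All rasters in the pipeline live on a :class:`Grid`: a rectangular array of
square cells of known size (km) anchored at an origin. Row 0 is the top row
(northernmost), matching the ESRI ASCII grid convention used for on-disk
storage. Cells are addressed ``(row, col)`` and each cell contributes equal
area to every fraction computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

__all__ = ["Grid", "GridMismatchError", "distance_raster"]


class GridMismatchError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster: shape, cell size and origin.

    Parameters
    ----------
    rows, cols
        Number of rows / columns.
    cell_km
        Edge length of a (square) cell in kilometres.
    x0, y_top
        Coordinates of the grid's top-left corner, in km.
    """

    rows: int
    cols: int
    cell_km: float = 1.0
    x0: float = 0.0
    y_top: float | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_km <= 0:
            raise ValueError("cell size must be positive")
        if self.y_top is None:
            object.__setattr__(self, "y_top", self.rows * self.cell_km)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def y_bottom(self) -> float:
        return self.y_top - self.rows * self.cell_km

    @property
    def x_right(self) -> float:
        return self.x0 + self.cols * self.cell_km

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` arrays of cell-center coordinates, shape (rows, cols)."""
        xs = self.x0 + (np.arange(self.cols) + 0.5) * self.cell_km
        ys = self.y_top - (np.arange(self.rows) + 0.5) * self.cell_km
        return np.meshgrid(xs, ys)

    def validate_array(self, values: np.ndarray, name: str = "raster") -> None:
        if values.shape != self.shape:
            raise GridMismatchError(
                f"{name} has shape {values.shape}, grid expects {self.shape}"
            )

    def require_same(self, other: "Grid", what: str = "rasters") -> None:
        if self != other:
            raise GridMismatchError(
                f"{what} are on different grids: {self} vs {other}"
            )


def distance_raster(lines, grid: Grid) -> np.ndarray:
    """Distance (km) from every cell center to the nearest of ``lines``.

    ``lines`` is a shapely geometry or an iterable of geometries (typically
    LineStrings for roads/railways/waterways). Returns ``inf`` everywhere if
    no geometry is given.
    """
    geoms = list(lines) if not isinstance(lines, shapely.Geometry) else [lines]
    x, y = grid.cell_centers()
    out = np.full(grid.shape, np.inf)
    if not geoms:
        return out
    pts = shapely.points(x.ravel(), y.ravel())
    merged = shapely.union_all(np.asarray(geoms, dtype=object))
    out = shapely.distance(pts, merged).reshape(grid.shape)
    return out
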