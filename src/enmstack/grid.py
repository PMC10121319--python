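"""Planar landscape grid shared by every pipeline stage.

The analysis runs on a flat, equal-area raster grid: cells are squares whose
area is expressed in hectares, and coordinates are planar metres (x east,
y north, origin at the lower-left corner).  Real-data use therefore requires
pre-projected equal-area rasters; the synthetic world is flat by construction.

The grid is partitioned into ``n_basins`` contiguous vertical bands.  Basins
play the role of the drainage basins used as sampling strata when floras are
drawn: they carry no environmental meaning of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LandscapeGrid"]


@dataclass(frozen=True)
class LandscapeGrid:
    """A rectangular grid of square cells with basin (stratum) labels.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be >= 1.
    cell_area
        Area of one cell in hectares (> 0).  The cell side length in metres
        is ``sqrt(cell_area * 1e4)``.
    origin
        (x, y) of the lower-left corner of the grid, in metres.
    n_basins
        Number of contiguous vertical bands partitioning the columns.
    """

    n_rows: int
    n_cols: int
    cell_area: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    n_basins: int = 3
    basin_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if not (1 <= self.n_basins <= self.n_cols):
            raise ValueError("n_basins must be between 1 and n_cols")
        if not self.basin_names:
            object.__setattr__(
                self,
                "basin_names",
                tuple(f"basin-{i + 1}" for i in range(self.n_basins)),
            )
        if len(self.basin_names) != self.n_basins:
            raise ValueError("basin_names length must equal n_basins")

    # -- geometry -----------------------------------------------------------

    @property
    def cell_size(self) -> float:
        """Cell side length in metres."""
        return float(np.sqrt(self.cell_area * 1e4))

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid, metres."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def cell_id(self, row: np.ndarray | int, col: np.ndarray | int) -> np.ndarray | int:
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        cid = np.asarray(cell_id)
        return cid // self.n_cols, cid % self.n_cols

    def cell_of_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell id containing each planar point; points must lie on the grid."""
        x0, y0, x1, y1 = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any((x < x0) | (x > x1) | (y < y0) | (y > y1)):
            raise ValueError("coordinates fall outside the grid")
        col = np.clip(((x - x0) // self.cell_size).astype(int), 0, self.n_cols - 1)
        row = np.clip(((y - y0) // self.cell_size).astype(int), 0, self.n_rows - 1)
        return self.cell_id(row, col)

    def cell_center(self, cell_id: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        row, col = self.rowcol(cell_id)
        x0, y0 = self.origin
        cs = self.cell_size
        return x0 + (np.asarray(col) + 0.5) * cs, y0 + (np.asarray(row) + 0.5) * cs

    # -- basins -------------------------------------------------------------

    def basin_of_col(self, col: np.ndarray | int) -> np.ndarray:
        """Basin index of each column (equal vertical bands, remainder eastward)."""
        edges = np.linspace(0, self.n_cols, self.n_basins + 1)
        return np.clip(
            np.searchsorted(edges, np.asarray(col), side="right") - 1,
            0,
            self.n_basins - 1,
        )

    def basin_of_cell(self, cell_id: np.ndarray | int) -> np.ndarray:
        _, col = self.rowcol(cell_id)
        return self.basin_of_col(col)

    def basin_extent(self, basin: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one basin band, metres."""
        edges = np.linspace(0, self.n_cols, self.n_basins + 1)
        x0, y0, _, y1 = self.extent
        cs = self.cell_size
        c0, c1 = int(np.floor(edges[basin])), int(np.floor(edges[basin + 1]))
        if basin == self.n_basins - 1:
            c1 = self.n_cols
        return (x0 + c0 * cs, y0, x0 + c1 * cs, y1)

    def basin_area_ha(self, basin: int) -> float:
        bx0, by0, bx1, by1 = self.basin_extent(basin)
        return (bx1 - bx0) * (by1 - by0) / 1e4
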