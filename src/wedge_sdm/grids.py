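"""Planar grids and stacks of environmental predictor layers.

Everything downstream works on a rectangular planar grid with unit-square
(or ``cell_size``-square) cells, 0-based row-major cell ids, and half-open
cell intervals [x0, x0+w) x [y0, y0+h).  Coordinates are planar: ``x`` plays
the role of longitude and ``y`` of latitude.  No geographic projection is
modelled; a coarse calibration grid and a fine projection grid are simply
two nested planar grids sharing the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Grid:
    """Rectangular planar grid with row-major 0-based cell ids."""

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def cell_id(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_centers(self, cell_id: np.ndarray | None = None) -> np.ndarray:
        """(n, 2) array of (x, y) centers, all cells by default."""
        if cell_id is None:
            cell_id = np.arange(self.n_cells)
        row, col = self.rowcol(cell_id)
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 + (np.asarray(row) + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map points to cell ids; -1 for points outside the grid.

        Cells are the half-open squares [x0+j*w, x0+(j+1)*w) etc., so a point
        on a shared edge belongs to the cell whose lower-left corner it
        touches.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(ok, row * self.n_cols + col, -1)
        return out


@dataclass
class EnvStack:
    """Named predictor layers on a common grid with a cell validity mask.

    ``data`` has shape (n_layers, n_rows, n_cols); ``mask`` is True on valid
    cells.
    """

    grid: Grid
    names: list[str]
    data: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_layers, n_rows, n_cols)")
        if self.data.shape != (len(self.names), self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with names/grid"
            )
        if self.mask is None:
            self.mask = np.ones((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("mask shape inconsistent with grid")

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def flat(self) -> np.ndarray:
        """(n_cells, n_layers) values in cell-id order."""
        return self.data.reshape(self.n_layers, -1).T

    def values_at(self, cell_ids: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """(len(cell_ids), len(names)) predictor values."""
        names = self.names if names is None else names
        idx = [self.names.index(n) for n in names]
        return self.data.reshape(self.n_layers, -1)[idx][:, np.asarray(cell_ids)].T

    def to_frame(self, cell_ids: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
        names = self.names if names is None else names
        return pd.DataFrame(self.values_at(cell_ids, names), columns=names)

    def subset(self, names: list[str]) -> "EnvStack":
        idx = [self.names.index(n) for n in names]
        return EnvStack(self.grid, list(names), self.data[idx].copy(), self.mask.copy())

    def aggregate(self, factor: int) -> "EnvStack":
        """Block-mean aggregation to a coarser grid (dimensions must divide)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        nr, nc = self.grid.n_rows, self.grid.n_cols
        if nr % factor or nc % factor:
            raise ValueError("grid dimensions must be divisible by factor")
        coarse = Grid(nr // factor, nc // factor, self.grid.cell_size * factor,
                      self.grid.x0, self.grid.y0)
        blocks = self.data.reshape(self.n_layers, coarse.n_rows, factor,
                                   coarse.n_cols, factor)
        data = blocks.mean(axis=(2, 4))
        m = self.mask.reshape(coarse.n_rows, factor, coarse.n_cols, factor)
        mask = m.any(axis=(1, 3))
        return EnvStack(coarse, list(self.names), data, mask)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            data=self.data,
            mask=self.mask,
            names=np.array(self.names),
            grid=np.array([self.grid.n_rows, self.grid.n_cols,
                           self.grid.cell_size, self.grid.x0, self.grid.y0]),
        )

    @classmethod
    def load_npz(cls, path) -> "EnvStack":
        with np.load(path, allow_pickle=False) as f:
            nr, nc, cs, x0, y0 = f["grid"]
            grid = Grid(int(nr), int(nc), float(cs), float(x0), float(y0))
            return cls(grid, [str(n) for n in f["names"]], f["data"], f["mask"])
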