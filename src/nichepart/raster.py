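"""Categorical land-cover raster on a planar metric grid.

The raster is stored row-major with row 0 at the *top* (north), matching
the ESRI ASCII grid convention used for on-disk exchange. Class names are
kept in a JSON sidecar next to the ``.asc`` file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ConfigurationError

NODATA = -9999


class InputError(ValueError):
    """Raised when supplied data violate an operation's preconditions."""


@dataclass
class HabitatRaster:
    classes: tuple[str, ...]
    grid: np.ndarray          # int class indices, shape (n_rows, n_cols)
    x0: float                 # west edge, m
    y0: float                 # south edge, m
    cell_m: float

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in meters."""
        return (self.x0, self.y0,
                self.x0 + self.n_cols * self.cell_m,
                self.y0 + self.n_rows * self.cell_m)

    def sample(self, x, y):
        """Class index under each (x, y); -1 for points outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_m).astype(int)
        row_from_south = np.floor((y - self.y0) / self.cell_m).astype(int)
        row = self.n_rows - 1 - row_from_south
        inside = (col >= 0) & (col < self.n_cols) & \
                 (row >= 0) & (row < self.n_rows)
        out = np.full(x.shape, -1, dtype=int)
        out[inside] = self.grid[row[inside], col[inside]]
        return out

    def class_proportions(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Realized availability: cell counts per class / total cells.

        ``mask`` optionally restricts to a boolean cell subset (study-area
        mask); an empty mask is an input error.
        """
        if mask is None:
            cells = self.grid.ravel()
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.grid.shape:
                raise InputError("mask shape does not match raster")
            if not mask.any():
                raise InputError("empty availability mask")
            cells = self.grid[mask]
        counts = np.bincount(cells, minlength=len(self.classes)).astype(float)
        return counts / counts.sum()

    def cell_centers_of_class(self, class_index: int) -> np.ndarray:
        """(n, 2) array of cell-center coordinates for one class."""
        rows, cols = np.nonzero(self.grid == class_index)
        x = self.x0 + (cols + 0.5) * self.cell_m
        y = self.y0 + (self.n_rows - 1 - rows + 0.5) * self.cell_m
        return np.column_stack([x, y])

    def write_ascii(self, path) -> None:
        path = Path(path)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x0:.6f}\n"
            f"yllcorner {self.y0:.6f}\n"
            f"cellsize {self.cell_m:.6f}\n"
            f"NODATA_value {NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.grid, fmt="%d")
        sidecar = path.with_suffix(path.suffix + ".classes.json")
        with open(sidecar, "w") as fh:
            json.dump({"classes": list(self.classes)}, fh, indent=1)

    @classmethod
    def read_ascii(cls, path) -> "HabitatRaster":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                meta[key.lower()] = float(value)
            grid = np.loadtxt(fh, dtype=int)
        grid = np.atleast_2d(grid)
        sidecar = path.with_suffix(path.suffix + ".classes.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                classes = tuple(json.load(fh)["classes"])
        else:
            classes = tuple(f"class_{i}" for i in range(int(grid.max()) + 1))
        if grid.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ConfigurationError("ASCII grid shape does not match header")
        return cls(classes=classes, grid=grid,
                   x0=meta["xllcorner"], y0=meta["yllcorner"],
                   cell_m=meta["cellsize"])
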