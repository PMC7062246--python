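"""Minimal planar raster grids with text (ESRI ASCII) I/O.

Grids are stored as 2-D float arrays with ``numpy.nan`` as the nodata
marker.  Row 0 is the northernmost row.  Cell ownership is half-open:
a point with easting ``x`` belongs to column ``floor((x - x0) / cell_size)``
and to the row whose *bottom-up* index is ``floor((y - y0) / cell_size)``,
so a point sitting exactly on a vertical cell edge belongs to the cell on
its right and a point on a horizontal edge to the cell above it (larger y).
This single convention is applied everywhere points meet grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

NODATA = -9999.0


class RasterAlignmentError(ValueError):
    """Raised when two grids that must share a geometry do not."""


@dataclass
class RasterGrid:
    """A single-band raster on a planar grid.

    Parameters
    ----------
    values:
        2-D float array, ``nan`` where nodata.  Row 0 is the top
        (northern) row.
    x0, y0:
        Map coordinates of the lower-left corner of the grid.
    cell_size:
        Edge length of the (square) cells, in map units.
    crs_id:
        Free-text identifier of the planar reference system.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 90.0
    crs_id: str = "synthetic-planar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs_id == other.crs_id
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates -> (row, col) under the half-open convention.

        Returned indices may fall outside the grid; callers check bounds.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row_bottom_up = np.floor((y - self.y0) / self.cell_size).astype(int)
        row = self.nrows - 1 - row_bottom_up
        return row, col

    def in_bounds(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center-coordinate arrays, each of shape ``self.shape``."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def center_of_cell(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    # -- sampling -----------------------------------------------------
    def sample(self, x, y) -> np.ndarray:
        """Values at map coordinates; nan for out-of-bounds points."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.cell_of(x, y)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(x.shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid with this geometry and the given values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise RasterAlignmentError(
                f"values shape {values.shape} != grid shape {self.shape}"
            )
        return RasterGrid(values, self.x0, self.y0, self.cell_size, self.crs_id)

    # -- I/O ----------------------------------------------------------
    def write_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        vals = np.where(np.isnan(self.values), NODATA, self.values)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {NODATA!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, crs_id: str = "synthetic-planar") -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh, ndmin=2)
        nodata = header.get("nodata_value", NODATA)
        vals[vals == nodata] = np.nan
        grid = cls(
            vals,
            x0=header["xllcorner"],
            y0=header["yllcorner"],
            cell_size=header["cellsize"],
            crs_id=crs_id,
        )
        if grid.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(f"header/body shape mismatch in {path}")
        return grid


@dataclass
class RasterStack:
    """Named collection of co-registered :class:`RasterGrid` layers."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.layers)
        for name in names[1:]:
            if not self.layers[name].same_geometry(self.layers[names[0]]):
                raise RasterAlignmentError(
                    f"layer {name!r} does not align with {names[0]!r}"
                )

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def add(self, name: str, grid: RasterGrid) -> None:
        if self.layers and not grid.same_geometry(self.template):
            raise RasterAlignmentError(f"layer {name!r} does not align with stack")
        self.layers[name] = grid

    def subset(self, names) -> "RasterStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack lacks layers: {missing}")
        return RasterStack({n: self.layers[n] for n in names})

    def sample(self, x, y, names=None) -> np.ndarray:
        """Matrix of layer values at points: shape (npoints, nlayers)."""
        names = list(names) if names is not None else self.names
        cols = [self[n].sample(x, y) for n in names]
        return np.column_stack(cols)

    def valid_mask(self, names=None) -> np.ndarray:
        names = list(names) if names is not None else self.names
        mask = np.ones(self.template.shape, dtype=bool)
        for n in names:
            mask &= ~np.isnan(self[n].values)
        return mask

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, RasterGrid]) -> "RasterStack":
        return cls(dict(mapping))
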