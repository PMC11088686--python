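"""Gridded spatial containers and plain-text raster I/O.

The analysis frame is a regular rectangular lattice of square cells with an
optional validity mask (nodata cells are excluded from every statistic).
Rasters are stored row-major with row 0 at the *top* of the map, matching the
ESRI ASCII grid convention used for on-disk exchange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class RasterGrid:
    """A rectangular cell lattice: origin, cell size and validity mask.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice dimensions.
    x_min, y_min : float
        Coordinates of the lower-left corner (``xllcorner``/``yllcorner``).
    cell_size : float
        Side length of each (square) cell, in map units.
    mask : ndarray of bool, optional
        ``True`` where the cell is part of the study area. Defaults to all
        cells valid.
    """

    n_rows: int
    n_cols: int
    x_min: float = 0.0
    y_min: float = 0.0
    cell_size: float = 1.0
    mask: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            object.__setattr__(self, "mask", np.ones((self.n_rows, self.n_cols), dtype=bool))
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (self.n_rows, self.n_cols):
                raise ValueError("mask shape does not match grid dimensions")
            object.__setattr__(self, "mask", m)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_min + (col + 0.5) * self.cell_size
        y = self.y_min + (self.n_rows - row - 0.5) * self.cell_size
        return (x, y)

    def cell_centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of cell-center coordinates, row-major."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        x = self.x_min + (cols + 0.5) * self.cell_size
        y = self.y_min + (self.n_rows - rows - 0.5) * self.cell_size
        return np.column_stack([x.ravel(), y.ravel()])

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/col of the cell containing (x, y); None if outside the lattice."""
        col = int(np.floor((x - self.x_min) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - self.y_min) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def points_to_cells(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point→(row, col); rows of -1 mark points off the lattice."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        col = np.floor((pts[:, 0] - self.x_min) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((pts[:, 1] - self.y_min) / self.cell_size).astype(int)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.full((len(pts), 2), -1, dtype=int)
        out[ok, 0] = row[ok]
        out[ok, 1] = col[ok]
        return out

    def cell_polygon(self, row: int, col: int):
        """Shapely box of one cell (lazy import keeps shapely optional here)."""
        from shapely.geometry import box

        x0 = self.x_min + col * self.cell_size
        y1 = self.y_min + (self.n_rows - row) * self.cell_size
        return box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)


def raster_values_at(values: np.ndarray, grid: RasterGrid, points: np.ndarray) -> np.ndarray:
    """Sample a raster at point locations (NaN for points off-grid/nodata)."""
    rc = grid.points_to_cells(points)
    out = np.full(len(rc), np.nan)
    ok = rc[:, 0] >= 0
    out[ok] = np.asarray(values, dtype=float)[rc[ok, 0], rc[ok, 1]]
    return out


# -- ESRI ASCII grid I/O ---------------------------------------------------

def write_ascii(path, values: np.ndarray, grid: RasterGrid) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, deterministic)."""
    vals = np.asarray(values, dtype=float).copy()
    vals[~grid.mask] = NODATA
    vals[np.isnan(vals)] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min!r}\n")
        fh.write(f"yllcorner {grid.y_min!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii(path) -> tuple[np.ndarray, RasterGrid]:
    """Read an ESRI ASCII grid; returns (values with NaN nodata, grid)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    vals = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", NODATA)
    mask = vals != nodata
    vals[~mask] = np.nan
    grid = RasterGrid(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        x_min=header.get("xllcorner", 0.0),
        y_min=header.get("yllcorner", 0.0),
        cell_size=header.get("cellsize", 1.0),
        mask=mask,
    )
    return vals, grid


def categorical_to_geojson(path, values: np.ndarray, grid: RasterGrid,
                           labels: dict[int, str]) -> None:
    """Dissolve a categorical raster into polygons and write GeoJSON."""
    from shapely.geometry import mapping
    from shapely.ops import unary_union

    features = []
    vals = np.asarray(values)
    for code in sorted(labels):
        cells = [
            grid.cell_polygon(r, c)
            for r, c in zip(*np.nonzero((vals == code) & grid.mask))
        ]
        if not cells:
            continue
        geom = unary_union(cells)
        features.append({
            "type": "Feature",
            "properties": {"category": labels[code], "code": int(code)},
            "geometry": mapping(geom),
        })
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
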