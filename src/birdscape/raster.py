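"""Categorical land-cover rasters and ESRI ASCII Grid I/O.

A :class:`RasterLandscape` is a dated 30-m categorical grid with the three
land-cover classes the analysis distinguishes: forest, exurban development,
and everything else.  Grids are stored row 0 = northernmost row, matching
the ESRI ASCII Grid layout; world coordinates are planar metres with the
origin at the lower-left corner of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: class codes, closed set
OTHER = 0
FOREST = 1
EXURBAN = 2

CLASS_CODES = (OTHER, FOREST, EXURBAN)
CLASS_NAMES = {OTHER: "other", FOREST: "forest", EXURBAN: "exurban"}

_NODATA = -9999


@dataclass
class RasterLandscape:
    """Categorical land-cover grid at one time point.

    Parameters
    ----------
    grid
        2-D integer array of class codes (``OTHER``/``FOREST``/``EXURBAN``).
        Row 0 is the northernmost row.
    cell_size
        Cell side length in metres (> 0).
    origin
        ``(x, y)`` of the grid's lower-left corner in metres.
    date
        Year label of the classification.
    """

    grid: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    date: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        bad = np.setdiff1d(np.unique(self.grid), CLASS_CODES)
        if bad.size:
            raise ValueError(f"unknown class codes in grid: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster in metres."""
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.cell_size, y0 + nrows * self.cell_size)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """World coordinates of the centre of cell ``(row, col)``."""
        nrows = self.grid.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - row - 0.5) * self.cell_size
        return (x, y)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing world point ``(x, y)``."""
        nrows = self.grid.shape[0]
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = nrows - 1 - int(np.floor((y - self.origin[1]) / self.cell_size))
        if not (0 <= row < nrows and 0 <= col < self.grid.shape[1]):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return (row, col)

    def class_fraction(self, code: int) -> float:
        """Fraction of grid cells carrying class ``code``."""
        return float(np.mean(self.grid == code))


def write_ascii_grid(raster: RasterLandscape, path) -> None:
    """Write a raster as an ESRI ASCII Grid (.asc) text file."""
    nrows, ncols = raster.grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid.astype(int), fmt="%d")


def read_ascii_grid(path, date: int = 0) -> RasterLandscape:
    """Read an ESRI ASCII Grid file into a :class:`RasterLandscape`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    ncols = int(header.get("ncols", grid.shape[1]))
    nrows = int(header.get("nrows", grid.shape[0]))
    if grid.shape != (nrows, ncols):
        raise ValueError(
            f"grid shape {grid.shape} does not match header ({nrows}, {ncols})"
        )
    return RasterLandscape(
        grid=grid.astype(np.int8),
        cell_size=header.get("cellsize", 30.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        date=date,
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
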