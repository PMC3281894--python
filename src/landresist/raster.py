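"""Raster data model, ESRI ASCII grid I/O and study-region construction.

The raster substrate used throughout the package is a single-band grid of
floats in a projected (planar, metre) coordinate system.  Row 0 is the
northernmost row, following the ESRI ASCII grid convention.  No-data cells
are held internally as NaN and serialized as the grid's ``nodata`` sentinel.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

__all__ = [
    "Grid",
    "SiteSet",
    "StudyRegion",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_sites",
    "write_sites",
    "build_study_region",
]


class GridFormatError(ValueError):
    """Raised when an ASCII grid file violates the format contract."""


@dataclass
class Grid:
    """A georeferenced single-band raster.

    Parameters
    ----------
    values
        ``(nrows, ncols)`` float array; NaN marks no-data cells.  Row 0 is
        the northernmost row.
    xll, yll
        Easting / northing of the lower-left *corner* of the grid, metres.
    cellsize
        Cell edge length, metres; cells are square.
    nodata
        Sentinel written for NaN cells on serialization.
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 25.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if np.isinf(self.values).any():
            raise ValueError("grid values must be finite or NaN (no-data)")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        return ~np.isnan(self.values)

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """(x, y) of cell centre(s); vectorized over row/col arrays."""
        x = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        y = self.yll + (self.nrows - np.asarray(row) - 0.5) * self.cellsize
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        col = int(math.floor((x - self.xll) / self.cellsize))
        row = self.nrows - 1 - int(math.floor((y - self.yll) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids of x and y coordinates of every cell centre."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.cell_center(rows, cols)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    def same_georef(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.xll, other.xll)
            and math.isclose(self.yll, other.yll)
            and math.isclose(self.cellsize, other.cellsize)
        )


@dataclass
class SiteSet:
    """Named sampling sites with planar coordinates (metres)."""

    ids: list[str]
    x: np.ndarray
    y: np.ndarray
    landscape: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("site ids must be unique")
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValueError("ids, x and y must have equal length")
        if not self.landscape:
            self.landscape = [""] * len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def cells(self, grid: Grid) -> list[tuple[int, int]]:
        """Snap each site to the (row, col) of the cell containing it."""
        return [grid.cell_of(xi, yi) for xi, yi in zip(self.x, self.y)]


@dataclass
class StudyRegion:
    """Inside/outside mask derived from a buffered convex hull of sites.

    ``mask.values`` is 1.0 inside, NaN outside; georeferencing is taken
    from the template grid the region was built against.
    """

    mask: Grid
    buffer: float

    @property
    def inside(self) -> np.ndarray:
        return self.mask.valid

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    def clip(self, grid: Grid) -> Grid:
        """Set cells outside the region to no-data."""
        if not self.mask.same_georef(grid):
            raise ValueError("grid is not co-registered with the region mask")
        out = grid.copy()
        out.values[~self.inside] = np.nan
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                "yllcenter", "cellsize", "nodata_value")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid (.asc), the dialect Circuitscape consumes.

    Both ``xllcorner`` and ``xllcenter`` headers are accepted (the latter is
    converted to corner georeferencing).  Cells equal to the declared
    ``NODATA_value`` are flagged no-data and excluded from all downstream
    computation.
    """
    header: dict[str, float] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"malformed header line: {line!r}") from exc
        elif parts and re.match(r"^[-+0-9.eE]", parts[0]):
            break
        elif parts:
            raise GridFormatError(f"malformed header line: {line!r}")
    body_lines = lines[i:]

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"missing required header keyword {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2.0
    else:
        raise GridFormatError("missing xllcorner/xllcenter header")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2.0
    else:
        raise GridFormatError("missing yllcorner/yllcenter header")

    flat = np.array(" ".join(body_lines).split(), dtype=float)
    if flat.size != nrows * ncols:
        raise GridFormatError(
            f"expected {nrows}x{ncols}={nrows * ncols} values, found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    return Grid(values=values, xll=xll, yll=yll, cellsize=cellsize, nodata=nodata)


def _fmt(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_ascii_grid(grid: Grid, path) -> None:
    """Write an ESRI ASCII grid; always emits ``xllcorner`` georeferencing.

    Exactly-integral values are written without a decimal point so integer
    grids round-trip byte-stably.
    """
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {_fmt(grid.xll)}\n")
        fh.write(f"yllcorner {_fmt(grid.yll)}\n")
        fh.write(f"cellsize {_fmt(grid.cellsize)}\n")
        fh.write(f"NODATA_value {_fmt(grid.nodata)}\n")
        for row in grid.values:
            fh.write(
                " ".join(_fmt(grid.nodata) if np.isnan(v) else _fmt(v) for v in row)
            )
            fh.write("\n")


def read_sites(path) -> SiteSet:
    """Read a delimited site table with columns id, x, y[, landscape]."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "x", "y"):
        if required not in cols:
            raise ValueError(f"site table missing column {required!r}")
    landscape = (
        df[cols["landscape"]].astype(str).tolist() if "landscape" in cols else []
    )
    return SiteSet(
        ids=df[cols["id"]].astype(str).tolist(),
        x=df[cols["x"]].to_numpy(float),
        y=df[cols["y"]].to_numpy(float),
        landscape=landscape,
    )


def write_sites(sites: SiteSet, path) -> None:
    pd.DataFrame(
        {"id": sites.ids, "x": sites.x, "y": sites.y, "landscape": sites.landscape}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Study region

def build_study_region(sites: SiteSet, buffer: float, template: Grid) -> StudyRegion:
    """Minimum convex polygon of the sites dilated by ``buffer`` metres.

    A cell is inside iff its centre lies within the buffered hull; in
    addition the cell containing each site is always inside, so sites on
    the hull boundary never fall on no-data cells of clipped surfaces.
    """
    if len(sites) < 1:
        raise ValueError("at least one site is required")
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    hull = MultiPoint([tuple(p) for p in sites.xy]).convex_hull
    # fine circular approximation so the dilated boundary is close to the
    # true Euclidean buffer at cell-centre resolution
    region_geom = hull.buffer(buffer, quad_segs=64) if buffer > 0 else hull
    if buffer == 0 and len(sites) > 1 and len(set(zip(sites.x, sites.y))) == 1:
        raise ValueError("all sites coincident with zero buffer: degenerate region")

    xs, ys = template.center_coords()
    inside = shapely.intersects_xy(region_geom, xs.ravel(), ys.ravel()).reshape(
        template.values.shape
    )
    for r, c in sites.cells(template):
        inside[r, c] = True
    mask_values = np.where(inside, 1.0, np.nan)
    mask = Grid(
        values=mask_values,
        xll=template.xll,
        yll=template.yll,
        cellsize=template.cellsize,
        nodata=template.nodata,
    )
    return StudyRegion(mask=mask, buffer=buffer)
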