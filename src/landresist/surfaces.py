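"""Construction of landscape resistance surfaces.

Four families of per-cell resistance surfaces are supported, mirroring the
standard hypotheses of landscape genetics for fragmented woodland systems:

* ``UNIFORM`` — isolation-by-distance null: every cell resistance 1.
* ``TREE_1_k`` — binary tree-cover surfaces: treed cells 1, cleared cells k.
* ``HAB_1_k`` — binarized habitat-suitability surfaces: habitat 1, matrix k.
* ``<SP>_EO_<d>`` — expert-opinion land-cover surfaces: per-class resistance
  equal to the reciprocal of the mean expert-estimated probability that an
  individual traverses distance d of that land-cover class.

Resistance is a cost per unit distance; valid values lie in [1, 10000]
(10000 being the reciprocal of the minimum permissible traversal
probability 0.0001 in the elicitation instrument).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Grid, SiteSet, StudyRegion

__all__ = [
    "LandCover",
    "EO_CATEGORY",
    "ResistanceTable",
    "ResistanceSurface",
    "uniform_surface",
    "generalize_tree_cover",
    "classify_scattered_trees",
    "tree_surface",
    "binarize_sdm",
    "habitat_surface",
    "landcover_surface",
    "read_resistance_tables",
]


class LandCover(IntEnum):
    """The nine land-cover classes of the study system.

    The three cleared agricultural classes each have a scattered-tree
    variant, assigned where cleared land lies within a fixed radius of
    tree cover.
    """

    TREE = 1                  # native tree-cover
    PLANTATION = 2            # plantation / horticulture / pine
    URBAN = 3
    UNIMPROVED = 4            # unimproved pasture and native grassland
    IMPROVED = 5              # improved pasture
    ARABLE = 6                # arable / crop
    UNIMPROVED_SCATTERED = 7
    IMPROVED_SCATTERED = 8
    ARABLE_SCATTERED = 9


_AGRICULTURAL = (LandCover.UNIMPROVED, LandCover.IMPROVED, LandCover.ARABLE)
_SCATTERED_OF = {
    LandCover.UNIMPROVED: LandCover.UNIMPROVED_SCATTERED,
    LandCover.IMPROVED: LandCover.IMPROVED_SCATTERED,
    LandCover.ARABLE: LandCover.ARABLE_SCATTERED,
}

# Expert-opinion resistance tables are published over six merged categories;
# this maps each of the nine land-cover classes onto its table category.
EO_CATEGORY: dict[LandCover, str] = {
    LandCover.TREE: "native_tree",
    LandCover.PLANTATION: "horticulture_pine",
    LandCover.URBAN: "urban",
    LandCover.UNIMPROVED: "cleared_no_scattered",
    LandCover.IMPROVED: "cleared_no_scattered",
    LandCover.ARABLE: "cleared_no_scattered",
    LandCover.UNIMPROVED_SCATTERED: "unimproved_scattered",
    LandCover.IMPROVED_SCATTERED: "crop_improved_scattered",
    LandCover.ARABLE_SCATTERED: "crop_improved_scattered",
}

_CANONICAL_TREE_OFF = (2, 5, 10, 100)
_CANONICAL_HAB_OFF = (2, 10)
RESISTANCE_MAX = 10000.0


@dataclass
class ResistanceTable:
    """Mapping from land-cover category to resistance for one model code."""

    model_code: str
    mapping: dict[str, float]

    def __post_init__(self) -> None:
        for cls, r in self.mapping.items():
            if not np.isfinite(r) or r < 1:
                raise ValueError(
                    f"resistance for {cls!r} must be finite and >= 1, got {r}"
                )

    def __getitem__(self, key: str) -> float:
        return self.mapping[key]


@dataclass
class ResistanceSurface:
    """A per-cell resistance grid labelled with its model code."""

    grid: Grid
    model_code: str

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid]
        if vals.size and (vals.min() < 1 or vals.max() > RESISTANCE_MAX):
            raise ValueError(
                f"{self.model_code}: resistances must lie in [1, {RESISTANCE_MAX:g}]"
            )


def uniform_surface(region: StudyRegion, value: float = 1.0) -> ResistanceSurface:
    """Homogeneous resistance surface: the isolation-by-distance null."""
    if value <= 0:
        raise ValueError("resistance value must be positive")
    grid = region.mask.copy()
    grid.values[region.inside] = value
    return ResistanceSurface(grid=grid, model_code="UNIFORM")


def generalize_tree_cover(fine: Grid, coarse_cellsize: float = 25.0) -> Grid:
    """Coarsen a binary tree raster: a coarse cell is treed iff at least one
    fine tree-pixel centre falls within it.

    The coarse grid is aligned to the fine grid's lower-left corner; partial
    overlap at the north/east margins is handled by pixel-centre membership.
    """
    vals = fine.values[fine.valid]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("fine grid must be binary {0, 1}")
    if coarse_cellsize < fine.cellsize:
        raise ValueError("coarse cellsize must be >= fine cellsize")

    ncols_c = math.ceil(fine.ncols * fine.cellsize / coarse_cellsize)
    nrows_c = math.ceil(fine.nrows * fine.cellsize / coarse_cellsize)
    xs, ys = fine.center_coords()
    col_c = np.floor((xs - fine.xll) / coarse_cellsize).astype(int)
    row_c = nrows_c - 1 - np.floor((ys - fine.yll) / coarse_cellsize).astype(int)

    tree = np.zeros((nrows_c, ncols_c), dtype=float)
    covered = np.zeros((nrows_c, ncols_c), dtype=bool)
    valid = fine.valid
    np.logical_or.at(covered, (row_c[valid], col_c[valid]), True)
    treed = valid & (fine.values == 1.0)
    np.maximum.at(tree, (row_c[treed], col_c[treed]), 1.0)
    tree[~covered] = np.nan
    return Grid(
        values=tree,
        xll=fine.xll,
        yll=fine.yll,
        cellsize=coarse_cellsize,
        nodata=fine.nodata,
    )


def classify_scattered_trees(
    landcover: Grid, tree: Grid, radius: float = 50.0
) -> Grid:
    """Reassign cleared agricultural cells near tree cover to their
    scattered-tree variants.

    A cleared cell (unimproved / improved pasture or arable land) becomes
    the corresponding scattered-tree class when its centre lies within
    ``radius`` metres (centre-to-centre) of any tree cell, and the cell
    itself is not contiguous tree cover.  Other classes are unchanged.
    The operation is idempotent: scattered variants are already within
    radius of trees and are not agricultural source classes.
    """
    if not landcover.same_georef(tree):
        raise ValueError("land-cover and tree grids are not co-registered")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    treed = tree.valid & (tree.values == 1.0)
    out = landcover.copy()
    if not treed.any():
        return out
    # Euclidean distance from each cell centre to the nearest tree centre.
    dist = ndimage.distance_transform_edt(~treed, sampling=landcover.cellsize)
    near = dist <= radius
    for cls in _AGRICULTURAL:
        sel = (landcover.values == float(cls)) & near & ~treed
        out.values[sel] = float(_SCATTERED_OF[cls])
    return out


def _binary_surface(
    on: np.ndarray,
    grid: Grid,
    off_resistance: float,
    region: StudyRegion,
    model_code: str,
) -> ResistanceSurface:
    clipped = region.clip(grid)
    values = np.where(on, 1.0, float(off_resistance))
    values[~clipped.valid] = np.nan
    out = Grid(
        values=values,
        xll=grid.xll,
        yll=grid.yll,
        cellsize=grid.cellsize,
        nodata=grid.nodata,
    )
    return ResistanceSurface(grid=out, model_code=model_code)


def tree_surface(
    tree: Grid, off_resistance: float, region: StudyRegion
) -> ResistanceSurface:
    """Tree-cover resistance surface: treed cells 1, cleared cells
    ``off_resistance`` (canonically 2, 5, 10 or 100)."""
    if off_resistance <= 1:
        raise ValueError("off-tree resistance must exceed 1")
    if off_resistance not in _CANONICAL_TREE_OFF:
        warnings.warn(
            f"off-resistance {off_resistance} is outside the canonical set "
            f"{_CANONICAL_TREE_OFF}", stacklevel=2,
        )
    vals = tree.values[tree.valid]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("tree grid must be binary {0, 1}")
    code = f"TREE_1_{off_resistance:g}"
    return _binary_surface(tree.values == 1.0, tree, off_resistance, region, code)


def binarize_sdm(sdm: Grid, presences: SiteSet, absences: SiteSet) -> Grid:
    """Binarize a continuous habitat-suitability surface at the threshold
    maximizing diagnosticity, operationalized as Youden's J
    (sensitivity + specificity - 1).

    Candidate thresholds are the suitability values observed at the
    presence and absence evaluation points; cells with value >= t* are
    habitat.  Ties in J are broken toward the lower threshold (the more
    inclusive habitat map).
    """
    p_vals = np.array([sdm.values[r, c] for r, c in presences.cells(sdm)])
    a_vals = np.array([sdm.values[r, c] for r, c in absences.cells(sdm)])
    if p_vals.size == 0 or a_vals.size == 0:
        raise ValueError("at least one presence and one absence are required")
    if np.isnan(p_vals).any() or np.isnan(a_vals).any():
        raise ValueError("evaluation points fall on no-data cells")
    candidates = np.unique(np.concatenate([p_vals, a_vals]))
    if candidates.size == 1:
        raise ValueError("all evaluation values identical: threshold degenerate")
    best_t, best_j = None, -np.inf
    for t in candidates:  # ascending, so strict > keeps the lower tied threshold
        sens = float(np.mean(p_vals >= t))
        spec = float(np.mean(a_vals < t))
        j = sens + spec - 1.0
        if j > best_j:
            best_t, best_j = t, j
    out = sdm.copy()
    out.values[sdm.valid] = (sdm.values[sdm.valid] >= best_t).astype(float)
    return out


def habitat_surface(
    habitat: Grid, off_resistance: float, region: StudyRegion
) -> ResistanceSurface:
    """Habitat-suitability resistance surface: habitat cells 1, matrix cells
    ``off_resistance`` (canonically 2 or 10)."""
    if off_resistance <= 1:
        raise ValueError("off-habitat resistance must exceed 1")
    if off_resistance not in _CANONICAL_HAB_OFF:
        warnings.warn(
            f"off-resistance {off_resistance} is outside the canonical set "
            f"{_CANONICAL_HAB_OFF}", stacklevel=2,
        )
    vals = habitat.values[habitat.valid]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("habitat grid must be binary {0, 1}")
    code = f"HAB_1_{off_resistance:g}"
    return _binary_surface(habitat.values == 1.0, habitat, off_resistance, region, code)


def landcover_surface(
    landcover: Grid,
    table: ResistanceTable,
    region: StudyRegion,
    categories: dict[LandCover, str] = EO_CATEGORY,
) -> ResistanceSurface:
    """Assign each land-cover cell the resistance its class carries in the
    table (classes looked up through their merged table category)."""
    clipped = region.clip(landcover)
    values = np.full(landcover.values.shape, np.nan)
    present = np.unique(clipped.values[clipped.valid])
    for code in present:
        cls = LandCover(int(code))
        cat = categories[cls]
        if cat not in table.mapping:
            raise KeyError(
                f"class {cls.name} (category {cat!r}) missing from table "
                f"{table.model_code}"
            )
        values[clipped.values == code] = table.mapping[cat]
    out = Grid(
        values=values,
        xll=landcover.xll,
        yll=landcover.yll,
        cellsize=landcover.cellsize,
        nodata=landcover.nodata,
    )
    return ResistanceSurface(grid=out, model_code=table.model_code)


def read_resistance_tables(path) -> dict[str, ResistanceTable]:
    """Read a delimited table with columns model, class, resistance into
    one ResistanceTable per model code."""
    df = pd.read_csv(path)
    tables = {}
    for model, sub in df.groupby("model"):
        mapping = dict(zip(sub["class"], sub["resistance"].astype(float)))
        tables[str(model)] = ResistanceTable(model_code=str(model), mapping=mapping)
    return tables
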