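"""Pairwise effective distances on resistance rasters.

Two effective-distance models are implemented on the same weighted grid
graph:

* **Least-cost path (LCP)** — the minimum accumulated traversal cost over
  any 4- or 8-connected path, i.e. the cost-weighted shortest path.  The
  traversal cost of an edge between cells a and b is the mean of their
  per-cell resistances times the centre-to-centre distance
  (``cellsize`` for orthogonal steps, ``cellsize * sqrt(2)`` for
  diagonal steps).
* **Isolation-by-resistance (IBR)** — the two-point effective resistance
  of the raster treated as a resistor network, with per-edge electrical
  resistance equal to the mean of the two cell resistances (scaled by
  sqrt(2) on diagonals).  Current flows through *all* paths, so IBR never
  exceeds the LCP cost of the same graph divided by cellsize.

Effective resistances are obtained by solving the grounded graph
Laplacian with a sparse direct factorization, reused across all site
pairs: with node g grounded, R(i, j) = (e_i - e_j)^T L_g^{-1} (e_i - e_j).

The module also reproduces the circular-grid boundary experiment showing
how pairwise effective resistance inflates for points near an artificial
grid edge — the reason a buffered study region and a uniform-surface
circuit-theory null (CS_UNIFORM) are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .raster import Grid, SiteSet, StudyRegion
from .surfaces import ResistanceSurface, uniform_surface

__all__ = [
    "WeightedGridGraph",
    "PairwiseDistanceMatrix",
    "EdgeEffectCurve",
    "build_grid_graph",
    "least_cost_distances",
    "effective_resistances",
    "edge_effect_experiment",
    "run_model_suite",
]

_SQRT2 = math.sqrt(2.0)


@dataclass
class WeightedGridGraph:
    """Grid graph over the valid cells of a resistance surface.

    ``node_of`` maps (row, col) to a dense node index (-1 for no-data
    cells).  Edge arrays hold one entry per undirected edge; ``edge_r``
    is the electrical resistance (mean cell resistance, sqrt(2)-scaled on
    diagonals) and traversal cost is ``edge_r * cellsize``.
    """

    node_of: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    edge_u: np.ndarray
    edge_v: np.ndarray
    edge_r: np.ndarray
    cellsize: float

    @property
    def n_nodes(self) -> int:
        return len(self.rows)

    @property
    def n_edges(self) -> int:
        return len(self.edge_u)

    def cost_matrix(self) -> sparse.csr_matrix:
        """Symmetric sparse matrix of least-cost traversal costs."""
        w = self.edge_r * self.cellsize
        m = sparse.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([self.edge_u, self.edge_v]),
              np.concatenate([self.edge_v, self.edge_u]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return m.tocsr()

    def laplacian(self) -> sparse.csr_matrix:
        """Graph Laplacian with edge conductances 1 / edge_r."""
        g = 1.0 / self.edge_r
        n = self.n_nodes
        off = sparse.coo_matrix(
            (np.concatenate([g, g]),
             (np.concatenate([self.edge_u, self.edge_v]),
              np.concatenate([self.edge_v, self.edge_u]))),
            shape=(n, n),
        ).tocsr()
        deg = np.asarray(off.sum(axis=1)).ravel()
        return sparse.diags(deg) - off

    def adjacency(self) -> sparse.csr_matrix:
        ones = np.ones(self.n_edges)
        return sparse.coo_matrix(
            (np.concatenate([ones, ones]),
             (np.concatenate([self.edge_u, self.edge_v]),
              np.concatenate([self.edge_v, self.edge_u]))),
            shape=(self.n_nodes, self.n_nodes),
        ).tocsr()


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric site-by-site matrix of effective distances."""

    ids: list[str]
    values: np.ndarray
    model_code: str
    method: str  # LCP | IBR | GEOG | logGEOG

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match the site list")

    @property
    def label(self) -> str:
        return f"{self.model_code}:{self.method}"

    def pair_values(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        return np.array([self.values[i, j] for i, j in pairs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rec = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rec.append(
                    (self.ids[i], self.ids[j], self.values[i, j],
                     self.model_code, self.method)
                )
        return pd.DataFrame(
            rec, columns=["site_i", "site_j", "value", "model", "method"]
        )


@dataclass
class EdgeEffectCurve:
    """Effective resistance vs offset from the grid edge, at one separation."""

    separation: float
    offsets: np.ndarray
    resistances: np.ndarray


def build_grid_graph(
    surface: ResistanceSurface, neighbours: int = 8
) -> WeightedGridGraph:
    """Connect valid cells to their 4- or 8-neighbours with edge resistance
    equal to the arithmetic mean of the two cell resistances (times sqrt(2)
    for diagonal edges)."""
    if neighbours not in (4, 8):
        raise ValueError("neighbours must be 4 or 8")
    grid = surface.grid
    valid = grid.valid
    node_of = np.full(grid.values.shape, -1, dtype=np.int64)
    rr, cc = np.nonzero(valid)
    node_of[rr, cc] = np.arange(len(rr))

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbours == 8:
        offsets += [(1, 1, _SQRT2), (1, -1, _SQRT2)]

    us, vs, ws = [], [], []
    r_vals = grid.values
    for dr, dc, scale in offsets:
        r0 = slice(max(0, -dr), grid.nrows - max(0, dr))
        c0 = slice(max(0, -dc), grid.ncols - max(0, dc))
        r1 = slice(max(0, dr), grid.nrows - max(0, -dr))
        c1 = slice(max(0, dc), grid.ncols - max(0, -dc))
        both = valid[r0, c0] & valid[r1, c1]
        us.append(node_of[r0, c0][both])
        vs.append(node_of[r1, c1][both])
        ws.append((r_vals[r0, c0][both] + r_vals[r1, c1][both]) / 2.0 * scale)

    return WeightedGridGraph(
        node_of=node_of,
        rows=rr,
        cols=cc,
        edge_u=np.concatenate(us),
        edge_v=np.concatenate(vs),
        edge_r=np.concatenate(ws),
        cellsize=grid.cellsize,
    )


def _site_nodes(graph: WeightedGridGraph, sites: SiteSet, grid: Grid) -> np.ndarray:
    nodes = []
    for sid, (r, c) in zip(sites.ids, sites.cells(grid)):
        n = graph.node_of[r, c]
        if n < 0:
            raise ValueError(f"site {sid!r} falls on a no-data cell")
        nodes.append(n)
    return np.array(nodes, dtype=np.int64)


def least_cost_distances(
    surface: ResistanceSurface, sites: SiteSet, neighbours: int = 8
) -> PairwiseDistanceMatrix:
    """All-pairs least-cost distances between sites (Dijkstra on the
    cost-weighted grid graph).  Disconnected pairs are infinite."""
    graph = build_grid_graph(surface, neighbours)
    nodes = _site_nodes(graph, sites, surface.grid)
    dist = csgraph.dijkstra(graph.cost_matrix(), directed=False, indices=nodes)
    mat = dist[:, nodes]
    mat = (mat + mat.T) / 2.0  # numerically symmetric
    np.fill_diagonal(mat, 0.0)
    return PairwiseDistanceMatrix(
        ids=list(sites.ids), values=mat, model_code=surface.model_code, method="LCP"
    )


def _pairwise_effective_resistance(
    graph: WeightedGridGraph, nodes: np.ndarray
) -> np.ndarray:
    """Two-point effective resistances among ``nodes``.

    One node per connected component is grounded; the reduced Laplacian is
    factorized once (sparse LU) and reused for every source column.  Pairs
    in different components get infinite resistance.
    """
    n_comp, labels = csgraph.connected_components(graph.adjacency(), directed=False)
    k = len(nodes)
    out = np.full((k, k), np.inf)
    np.fill_diagonal(out, 0.0)
    lap = graph.laplacian().tocsc()

    for comp in np.unique(labels[nodes]):
        comp_nodes = np.nonzero(labels == comp)[0]
        sites_here = np.nonzero(labels[nodes] == comp)[0]
        if len(sites_here) < 2:
            continue
        ground = comp_nodes[-1]
        keep = comp_nodes[comp_nodes != ground]
        if keep.size == 0:  # single-cell component: all sites share one node
            for ia, a in enumerate(sites_here):
                for b in sites_here[ia + 1:]:
                    out[a, b] = out[b, a] = 0.0
            continue
        lap_red = lap[np.ix_(keep, keep)].tocsc()
        lu = splu(lap_red)
        pos = {node: idx for idx, node in enumerate(keep)}
        # one solve per distinct site node in this component
        sols: dict[int, np.ndarray] = {}
        for a in sites_here:
            node = nodes[a]
            if node == ground or node in sols:
                continue
            e = np.zeros(keep.size)
            e[pos[node]] = 1.0
            sols[node] = lu.solve(e)
        for ia, a in enumerate(sites_here):
            for b in sites_here[ia + 1:]:
                na, nb = nodes[a], nodes[b]
                if na == nb:
                    r = 0.0
                elif na == ground:
                    r = sols[nb][pos[nb]]
                elif nb == ground:
                    r = sols[na][pos[na]]
                else:
                    va, vb = sols[na], sols[nb]
                    r = va[pos[na]] - va[pos[nb]] - vb[pos[na]] + vb[pos[nb]]
                out[a, b] = out[b, a] = r
    return out


def effective_resistances(
    surface: ResistanceSurface, sites: SiteSet, neighbours: int = 8
) -> PairwiseDistanceMatrix:
    """All-pairs two-point effective resistances between sites on the
    resistor network of the surface (isolation-by-resistance)."""
    graph = build_grid_graph(surface, neighbours)
    nodes = _site_nodes(graph, sites, surface.grid)
    mat = _pairwise_effective_resistance(graph, nodes)
    return PairwiseDistanceMatrix(
        ids=list(sites.ids), values=mat, model_code=surface.model_code, method="IBR"
    )


def _disc_surface(radius: int) -> ResistanceSurface:
    """Uniform-resistance circular grid: cell size 1, resistance 1 per cell,
    cells whose centres lie within ``radius`` of the disc centre."""
    n = 2 * radius + 1
    idx = np.arange(n) - radius
    yy, xx = np.meshgrid(idx, idx, indexing="ij")
    inside = xx**2 + yy**2 <= radius**2
    values = np.where(inside, 1.0, np.nan)
    grid = Grid(values=values, xll=0.0, yll=0.0, cellsize=1.0)
    return ResistanceSurface(grid=grid, model_code="DISC_UNIFORM")


def edge_effect_experiment(
    radius: int,
    separations: list[int],
    offsets: list[int],
    neighbours: int = 8,
) -> list[EdgeEffectCurve]:
    """Quantify the boundary inflation of pairwise effective resistance.

    On a uniform circular grid (resistance 1 per cell, cell size 1), point
    pairs at geographic separation s are slid along a radius: the nearer
    point sits ``offset`` cells in from the disc edge, the farther point
    s cells beyond it toward (and possibly past) the centre.  Resistance
    rises as the pair approaches the edge, and the inflation reaches
    further inward for larger separations — which is why circuit-theory
    distances need a buffered grid and a uniform-surface null.
    """
    surface = _disc_surface(radius)
    grid = surface.grid
    for s in separations:
        for o in offsets:
            if o < 0 or s <= 0 or o + s > 2 * radius:
                raise ValueError(
                    f"pair (separation={s}, offset={o}) does not fit in the disc"
                )
    graph = build_grid_graph(surface, neighbours)
    centre = radius  # row/col index of the disc centre

    # nearer point at x = radius - offset (cells from centre along +x axis),
    # farther point s cells further in (may cross to negative x).
    positions: set[int] = set()
    pair_cols: dict[tuple[int, int], tuple[int, int]] = {}
    for s in separations:
        for o in offsets:
            near_col = centre + (radius - o)
            far_col = near_col - s
            pair_cols[(s, o)] = (near_col, far_col)
            positions.update((near_col, far_col))

    cols = sorted(positions)
    nodes = np.array([graph.node_of[centre, c] for c in cols], dtype=np.int64)
    if (nodes < 0).any():
        raise ValueError("a pair endpoint falls outside the disc")
    res = _pairwise_effective_resistance(graph, nodes)
    col_idx = {c: i for i, c in enumerate(cols)}

    curves = []
    for s in separations:
        offs = np.array(sorted(offsets), dtype=float)
        vals = np.array(
            [res[col_idx[pair_cols[(s, o)][0]], col_idx[pair_cols[(s, o)][1]]]
             for o in sorted(offsets)]
        )
        curves.append(EdgeEffectCurve(separation=float(s), offsets=offs,
                                      resistances=vals))
    return curves


def geographic_matrix(sites: SiteSet, log_transform: bool = False
                      ) -> PairwiseDistanceMatrix:
    # implemented in comparison.py; re-exported there (import kept lazy to
    # avoid a cycle)
    from .comparison import geographic_distances

    return geographic_distances(sites, log_transform)


def run_model_suite(
    surfaces: list[ResistanceSurface],
    sites: SiteSet,
    region: StudyRegion,
    neighbours: int = 8,
) -> list[PairwiseDistanceMatrix]:
    """Compute the full matrix suite: LCP and IBR per surface, plus the
    three null matrices GEOG, logGEOG and CS_UNIFORM (the IBR of a uniform
    surface over the same region, carrying the same boundary inflation)."""
    from .comparison import geographic_distances

    out: list[PairwiseDistanceMatrix] = []
    for surf in surfaces:
        out.append(least_cost_distances(surf, sites, neighbours))
        out.append(effective_resistances(surf, sites, neighbours))
    out.append(geographic_distances(sites, log_transform=False))
    out.append(geographic_distances(sites, log_transform=True))
    cs_uniform = effective_resistances(uniform_surface(region), sites, neighbours)
    cs_uniform.model_code = "CS_UNIFORM"
    out.append(cs_uniform)
    ids0 = out[0].ids
    assert all(m.ids == ids0 for m in out)
    return out
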