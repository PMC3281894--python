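import numpy as np
import pytest
from hypothesis import settings

import landresist as lr

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_surface_10():
    """10x10 uniform surface, resistance 1, cellsize 1."""
    grid = lr.Grid(values=np.ones((10, 10)), xll=0, yll=0, cellsize=1)
    return lr.ResistanceSurface(grid=grid, model_code="UNIFORM")


def random_surface(rng, shape, choices=(1.0, 5.0), cellsize=1.0, nodata_frac=0.0):
    values = rng.choice(choices, size=shape).astype(float)
    if nodata_frac > 0:
        mask = rng.uniform(size=shape) < nodata_frac
        values[mask] = np.nan
    grid = lr.Grid(values=values, xll=0, yll=0, cellsize=cellsize)
    return lr.ResistanceSurface(grid=grid, model_code="RAND")


def corner_sites(grid, n=2):
    """Sites at the first n valid cell centres scanning row-major."""
    rows, cols = np.nonzero(grid.valid)
    xs, ys = grid.cell_center(rows[:n], cols[:n])
    return lr.SiteSet(ids=[f"s{i}" for i in range(n)], x=xs, y=ys)


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)

def dense_effective_resistance(graph, node_a, node_b):
    """Two-point effective resistance via the dense Moore-Penrose
    pseudo-inverse of the full graph Laplacian."""
    lap = graph.laplacian().toarray()
    lp = np.linalg.pinv(lap, hermitian=True)
    return lp[node_a, node_a] + lp[node_b, node_b] - 2 * lp[node_a, node_b]


def floyd_warshall_distances(graph):
    """All-pairs shortest path by exhaustive relaxation on the dense cost
    matrix (independent of scipy's Dijkstra path)."""
    n = graph.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    w = graph.edge_r * graph.cellsize
    for u, v, c in zip(graph.edge_u, graph.edge_v, w):
        d[u, v] = min(d[u, v], c)
        d[v, u] = min(d[v, u], c)
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d
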