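# Methods

## Raster substrate

All surfaces are single-band rasters in a projected metre coordinate
system, row 0 northernmost, serialized as ESRI ASCII grids (the dialect
circuit-theory tools consume). Both `xllcorner` and `xllcenter`
georeferencing are accepted on read; `xllcorner` is always written, and
exactly-integral values are written without a decimal point so integer
grids round-trip byte-stably. No-data cells are held as NaN internally
and excluded from every computation. Reprojection, datum handling and
multi-band rasters are out of scope; coordinates are assumed planar.

The study region is the minimum convex polygon of the site points
dilated by a buffer (default 25 km in the study design; the buffer
exists to push the artificial grid boundary away from the sites, see
*Edge effect* below). Cell membership uses the cell-centre test; the
cell containing each site is additionally always inside, so sites on the
hull boundary never land on no-data cells. The circular dilation is
approximated with 64 segments per quadrant, accurate to well under one
cell at 25 m resolution. The hull is computed on site points (the
natural reading when only point data are available).

## Resistance surfaces

Per-cell resistances are costs per unit distance, constrained to
`[1, 10000]`; 10000 is the reciprocal of the elicitation floor
probability 0.0001.

* **Tree generalization (10 m → 25 m).** A coarse cell is treed iff at
  least one fine tree-pixel *centre* falls inside it; pixel-centre
  membership resolves the partial-overlap ambiguity of the non-integer
  cell-size ratio, and makes the operation monotone in the fine pixels.
* **Scattered trees.** Cleared agricultural cells (unimproved pasture,
  improved pasture, arable land) whose centre lies within 50 m
  (centre-to-centre, via a Euclidean distance transform) of a tree-cell
  centre, and which are not themselves tree cover, become the
  corresponding scattered-tree class. "Contiguous tree cover" is read
  as "the cell itself is treed in the generalized tree grid" (no
  patch-size criterion is imposed). The operation is idempotent.
* **Suitability binarization.** The threshold maximizes Youden's J
  (sensitivity + specificity − 1) over the candidate set of suitability
  values observed at the presence/absence evaluation points; ties break
  toward the lower threshold (the more inclusive habitat map). Habitat
  is `value ≥ t*`.
* **Canonical off-resistances** are {2, 5, 10, 100} for tree surfaces
  and {2, 10} for habitat surfaces; other values are permitted for
  sensitivity analyses but warn.
* **Expert-opinion surfaces** look up each of the nine land-cover
  classes through its merged table category (the published tables are
  stated over six categories: native tree cover, horticulture/pine,
  unimproved pasture with scattered trees, crop/improved pasture with
  scattered trees, cleared land without scattered trees, urban). The
  published per-model tables ship as a package fixture
  (`landresist.data/resistance_tables.csv`).

## Effective distances

The grid graph connects valid cells to 8 (default) or 4 neighbours.
Edge electrical resistance is the arithmetic mean of the two cell
resistances, × √2 on diagonals; least-cost traversal cost is the same ×
cell size. This is the standard raster-circuit convention of the widely
used tools; the harmonic-mean alternative could be added behind the same
interface. Sites snap to the cell containing their coordinates.

LCP distances are Dijkstra shortest paths on the cost graph (sparse
`csgraph`). IBR distances ground one node per connected component,
factorize the reduced Laplacian once with sparse LU, solve one column
per distinct site node, and assemble
`R(i,j) = v_i[i] − v_i[j] − v_j[i] + v_j[j]`. A direct factorization is
used deliberately: results carry no iterative-solver tolerance.
Disconnected pairs are reported as `inf`, never as a large finite
sentinel. Desk scale targets grids up to ~10⁶ cells.

## Edge effect

On a uniform disc (resistance 1, cell size 1) pairs are slid along a
radius: the nearer point at a given offset from the edge, the farther
point a fixed separation further in. Pairwise effective resistance
inflates as the pair approaches the boundary, and the inflation reaches
further inward for larger separations. Tests verify both qualitative
facts and exact agreement (1e-8) with a dense Laplacian pseudo-inverse
oracle on small discs. This inflation is why (a) study regions are
buffered, and (b) the recommended null for IBR models is `CS_UNIFORM`
(IBR of the uniform surface on the same grid, carrying the same
inflation) while for LCP models it is plain geographic distance.
The test-side oracle uses `pinv(..., hermitian=True)`; the generic SVD
path is observably less accurate on these Laplacians.

## Independent-pair bootstrap

Each iteration pairs off a fresh random permutation of the sites,
yielding ⌊n/2⌋ disjoint pairs (with odd n the unused site varies across
iterations); the statistic is the squared Pearson correlation of the
selected matrix entries, summarized by the mean and the 2.5/97.5
empirical percentiles over iterations (the interval method is a
package choice; percentiles are distribution-free). Iterations with
zero variance or non-finite entries are discarded and counted. Under
independence the expected R² for k pairs is ≈ 1/(k−1), which the tests
verify at k = 10. Pearson on raw distances is used (rank-transformed
variants would fit behind the same interface). Mantel and partial-Mantel
testing against genetic data is explicitly out of scope.

Predicted per-species model rankings (ties allowed; species codes BT,
EYR, FH, GST, SFW, SPP, STP, WB, WPH, YTH) ship as a fixture and are
scored against observed mean R² values by Spearman correlation with
midrank ties. Panmixia (no spatial structure) has no distance matrix; it
is evaluated against the independence baseline above.

## Expert elicitation

Mean conductivity is the arithmetic mean over experts per (species,
land-cover, distance); missing expert cells are dropped from the mean,
but a combination with no estimates at all is an error. Resistance is
the reciprocal, mapping `[0.0001, 1]` onto `[1, 10000]`. Classes with
equal resistance are merged (exact ties by default; a relative tolerance
is available for noisy synthetic panels). The canonical distance set is
{100, 200, 500, 1000, 2000, 5000, 10000} m — the seven-distance layout
of the published variance table; elicitation protocols that omit 2000 m
are accepted, since the panel type imposes no fixed distance set.

Variance components for the crossed random effects (expert, land-cover,
species, plus distance when pooling) are estimated by the ANOVA
(method-of-moments) estimator on main-effect mean squares of the
additive model, with negative estimates truncated at zero, then
renormalized to percentages of total. Probabilities enter untransformed.
This is *not* claimed to be REML-equivalent to a mixed-model package;
it is validated instead by parameter recovery: panels generated with
known shares (expert 20%, land-cover 30%, species 10%, residual 40%;
5 experts × 9 classes × 8 species) are recovered within ±5 percentage
points on the mean over 200 replicates.

## Synthetic data

The generators define the test conditions and mirror the study design:
10 × 10 km landscapes at 25 m (tests use smaller extents for speed, 1.2–5
km, which preserves every contract being tested), cover fractions
spanning 0.11–0.79, aggregated/dispersed/continuous configurations, 3–6
sites per landscape, five-expert panels.

* **Land cover** thresholds a Gaussian-smoothed white-noise field at the
  quantile realizing the target cover fraction (achieved within ±2
  points by construction); the smoothing length is the single
  aggregation knob (8 cells aggregated/continuous, 1.2 dispersed —
  aggregated landscapes have strictly fewer, larger patches at equal
  cover). Matrix cells are split among the agricultural classes by a
  second field, with small urban/plantation pockets. Continuous
  landscapes require cover ≥ 0.7.
* **Sites** are rejection-sampled cell centres with a minimum spacing,
  optionally restricted to treed cells.
* **Suitability surfaces** mix the standardized tree indicator with
  smooth noise under a fidelity weight and rescale to [0, 1].
* **Expert panels** draw zero-mean normal expert/land-cover/species
  effects whose variances realize the specified shares of a total
  variance (default 0.01), add them to true means that decay
  monotonically with distance, and clip to [0.0001, 1] (clipping, not
  re-drawing, mirrors the elicitation floor). A scalar `true_means`
  gives a flat panel for clean recovery tests.

What the generators do **not** emulate: real vegetation ecology (patch
shape, linear remnants, riparian strips), spatially autocorrelated
expert error, and any relationship between landscape structure and
genetic data — so green tests demonstrate the correctness of the
computational chain under its stated assumptions, not ecological
validity of any particular resistance hypothesis.

## Reproducibility and numerics

Every stochastic operation takes an explicit seeded generator or seed;
the pipeline runner derives per-stage substreams from one config seed
via `SeedSequence`, making reruns byte-identical. Degenerate inputs are
errors, not silent defaults (coincident sites with zero buffer,
non-binary tree grids, all-identical suitability scores, probability
bounds violations). The sizes used by the default test run (400 × 400
uniform grid for the least-cost null check, disc radius 60 for the edge
effect, 200 panels for variance recovery) are the package's chosen desk
scale; all scale up linearly behind the same interfaces.
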