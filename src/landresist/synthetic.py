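"""Synthetic landscapes, site sets, suitability surfaces and expert panels.

The generators emulate the structure of the study system — 10 x 10 km
agricultural mosaics at 25 m resolution with remnant native tree cover in
aggregated, dispersed or continuous configurations (landscape cover
fractions spanning roughly 11-79%), 3-6 sampling sites per landscape, and
five-expert panels of traversal probabilities over seven gap distances
and nine land-cover classes — so every stage of the pipeline can be
exercised end-to-end without any external data.

Tree cover is generated by thresholding a Gaussian-smoothed white-noise
field at the quantile that realizes the requested cover fraction; the
smoothing length is the single knob separating aggregated (long
correlation length, few large patches) from dispersed (short length, many
small patches) configurations.  Expert panels are drawn from an additive
crossed random-effects model with user-specified variance shares, so the
variance decomposition can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .elicitation import DISTANCES_M, PROB_MAX, PROB_MIN, ExpertPanel
from .raster import Grid, SiteSet
from .surfaces import LandCover

__all__ = [
    "LandscapeSpec",
    "PanelSpec",
    "simulate_landcover",
    "simulate_sites",
    "simulate_sdm",
    "simulate_expert_panel",
]

# smoothing length (cells) controlling tree-patch aggregation
_SIGMA = {"aggregated": 8.0, "dispersed": 1.2, "continuous": 8.0}


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic landscape."""

    extent: float = 10_000.0          # square landscape edge, metres
    cellsize: float = 25.0
    cover_fraction: float = 0.2
    configuration: str = "aggregated"  # aggregated | dispersed | continuous
    seed: int = 0
    cover_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.configuration not in _SIGMA:
            raise ValueError(
                "configuration must be aggregated, dispersed or continuous"
            )
        if not 0 <= self.cover_fraction <= 1:
            raise ValueError("cover_fraction must lie in [0, 1]")
        if self.configuration == "continuous" and self.cover_fraction < 0.7:
            raise ValueError("continuous landscapes require cover_fraction >= 0.7")
        n = self.extent / self.cellsize
        if abs(n - round(n)) > 1e-9:
            raise ValueError("extent must be an integer multiple of cellsize")

    @property
    def n_cells(self) -> int:
        return int(round(self.extent / self.cellsize))


def _smooth_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if sigma > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=sigma, mode="wrap")
    return field_


def _threshold_at_fraction(field_: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask selecting approximately ``fraction`` of cells (the
    highest field values; quantile thresholding)."""
    if fraction <= 0:
        return np.zeros(field_.shape, dtype=bool)
    if fraction >= 1:
        return np.ones(field_.shape, dtype=bool)
    k = int(round(fraction * field_.size))
    k = min(max(k, 1), field_.size)
    cutoff = np.partition(field_.ravel(), field_.size - k)[field_.size - k]
    return field_ >= cutoff


def simulate_landcover(spec: LandscapeSpec) -> tuple[Grid, Grid]:
    """Generate a nine-class land-cover grid and its binary tree grid.

    Returns ``(landcover, tree)``.  Tree cover realizes the requested
    fraction (within ``cover_tolerance``); non-treed cells are split among
    the three cleared agricultural classes by a second smoothed field,
    with a small urban nucleus and plantation fringe for class coverage.
    Scattered-tree variants are *not* assigned here — that is the
    pipeline's scattered-tree classification step.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    sigma = _SIGMA[spec.configuration]
    tree_mask = _threshold_at_fraction(
        _smooth_field((n, n), sigma, rng), spec.cover_fraction
    )
    achieved = tree_mask.mean()
    if abs(achieved - spec.cover_fraction) > spec.cover_tolerance:
        raise ValueError(
            f"achieved cover {achieved:.3f} misses target "
            f"{spec.cover_fraction:.3f} by more than {spec.cover_tolerance}"
        )

    # Partition the matrix among the cleared agricultural classes with a
    # second, independent smooth field; small urban/plantation pockets.
    agri_field = _smooth_field((n, n), 4.0, rng)
    q1, q2 = np.quantile(agri_field, [1 / 3, 2 / 3])
    values = np.full((n, n), float(LandCover.UNIMPROVED))
    values[agri_field >= q1] = float(LandCover.IMPROVED)
    values[agri_field >= q2] = float(LandCover.ARABLE)
    pocket = _smooth_field((n, n), 3.0, rng)
    values[_threshold_at_fraction(pocket, 0.02)] = float(LandCover.URBAN)
    values[_threshold_at_fraction(-pocket, 0.02)] = float(LandCover.PLANTATION)
    values[tree_mask] = float(LandCover.TREE)

    landcover = Grid(values=values, xll=0.0, yll=0.0, cellsize=spec.cellsize)
    tree = Grid(
        values=tree_mask.astype(float), xll=0.0, yll=0.0, cellsize=spec.cellsize
    )
    return landcover, tree


def simulate_sites(
    landcover: Grid,
    n_sites: int,
    min_spacing: float = 1000.0,
    require_tree: bool = True,
    seed: int = 0,
    tree: Grid | None = None,
    max_tries: int = 10_000,
    landscape: str = "L0",
) -> SiteSet:
    """Place sampling sites at cell centres, at least ``min_spacing``
    metres apart, optionally restricted to treed cells.

    Sites are drawn by rejection sampling; an infeasible spacing raises
    after ``max_tries`` candidate draws.
    """
    if not 1 <= n_sites:
        raise ValueError("n_sites must be positive")
    if require_tree:
        if tree is None:
            eligible = landcover.valid & (landcover.values == float(LandCover.TREE))
        else:
            eligible = tree.valid & (tree.values == 1.0)
    else:
        eligible = landcover.valid
    rows, cols = np.nonzero(eligible)
    if len(rows) < n_sites:
        raise ValueError("not enough eligible cells for the requested sites")
    rng = np.random.default_rng(seed)
    xs, ys = landcover.cell_center(rows, cols)
    chosen: list[int] = []
    tries = 0
    while len(chosen) < n_sites:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_sites} sites with spacing {min_spacing} m "
                f"in {max_tries} tries"
            )
        tries += 1
        cand = int(rng.integers(len(rows)))
        if cand in chosen:
            continue
        ok = all(
            math.hypot(xs[cand] - xs[c], ys[cand] - ys[c]) >= min_spacing
            for c in chosen
        )
        if ok:
            chosen.append(cand)
    return SiteSet(
        ids=[f"S{i + 1}" for i in range(n_sites)],
        x=xs[chosen],
        y=ys[chosen],
        landscape=[landscape] * n_sites,
    )


def simulate_sdm(tree: Grid, fidelity: float, seed: int = 0) -> Grid:
    """Synthetic habitat-suitability (probability of occurrence) surface.

    A ``fidelity``-weighted mix of the standardized tree indicator and an
    independent smooth noise field, min-max rescaled to [0, 1]; fidelity 1
    is rank-identical to the tree indicator, fidelity 0 is unrelated.
    """
    if not 0 <= fidelity <= 1:
        raise ValueError("fidelity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = tree.values.copy()
    valid = tree.valid
    tz = np.zeros_like(t)
    tv = t[valid]
    if tv.std() > 0:
        tz[valid] = (tv - tv.mean()) / tv.std()
    noise = _smooth_field(t.shape, 3.0, rng)
    nz = (noise - noise.mean()) / noise.std()
    mix = fidelity * tz + (1 - fidelity) * nz
    lo, hi = mix[valid].min(), mix[valid].max()
    probs = np.full(t.shape, np.nan)
    probs[valid] = 0.5 if hi == lo else (mix[valid] - lo) / (hi - lo)
    return Grid(
        values=probs, xll=tree.xll, yll=tree.yll,
        cellsize=tree.cellsize, nodata=tree.nodata,
    )


def _default_true_means(
    species: list[str], landcovers: list[str], distances: list[float]
) -> pd.DataFrame:
    """Traversal probability decaying with distance and modulated by land
    cover: treed classes are easy at all distances, cleared classes drop
    fast — the qualitative pattern of the elicitation."""
    ease = {lc: 1.0 - 0.8 * i / max(len(landcovers) - 1, 1)
            for i, lc in enumerate(landcovers)}
    rows = []
    for sp in species:
        for lc in landcovers:
            for d in distances:
                p = ease[lc] * math.exp(-d / 4000.0)
                rows.append((sp, lc, d, min(max(p, PROB_MIN), PROB_MAX)))
    return pd.DataFrame(
        rows, columns=["species", "landcover", "distance_m", "true_mean"]
    )


@dataclass
class PanelSpec:
    """Parameters of a synthetic expert panel.

    ``variance_shares`` gives the fraction of ``total_variance``
    attributed to each of the expert, land-cover and species random
    effects; the remainder is residual noise.  Estimates are the true
    mean plus the sampled effects, clipped to [0.0001, 1] (the
    elicitation instrument's floor and ceiling).
    """

    n_experts: int = 5
    species: list[str] = field(
        default_factory=lambda: ["BT", "EYR", "FH", "GST", "SFW", "WB", "WPH", "YTH"]
    )
    landcovers: list[str] = field(
        default_factory=lambda: [c.name.lower() for c in LandCover]
    )
    distances: list[float] = field(default_factory=lambda: list(DISTANCES_M))
    true_means: pd.DataFrame | float | None = None
    variance_shares: dict[str, float] = field(
        default_factory=lambda: {"expert": 0.1, "landcover": 0.1, "species": 0.05}
    )
    total_variance: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        extra = set(self.variance_shares) - {"expert", "landcover", "species"}
        if extra:
            raise ValueError(f"unknown variance components: {sorted(extra)}")
        shares = sum(self.variance_shares.values())
        if shares > 1 or any(v < 0 for v in self.variance_shares.values()):
            raise ValueError("variance shares must be non-negative and sum to <= 1")
        if self.true_means is None:
            self.true_means = _default_true_means(
                self.species, self.landcovers, self.distances
            )
        elif np.isscalar(self.true_means):
            # flat panel: all structure comes from the random effects, so
            # the variance decomposition can be validated by recovery
            mu = float(self.true_means)
            base = _default_true_means(self.species, self.landcovers, self.distances)
            base["true_mean"] = mu
            self.true_means = base

    @property
    def residual_share(self) -> float:
        return 1.0 - sum(self.variance_shares.values())


def simulate_expert_panel(spec: PanelSpec) -> ExpertPanel:
    """Draw an expert panel from the additive crossed random-effects model

    estimate = clip(true_mean + a_expert + b_landcover + c_species + eps,
                    0.0001, 1)

    with zero-mean normal effects whose variances realize the specified
    shares of ``total_variance``.  True means decrease monotonically with
    distance, so the distance signal enters through the means, not as a
    sampled effect.
    """
    rng = np.random.default_rng(spec.seed)
    sd = {
        k: math.sqrt(spec.variance_shares.get(k, 0.0) * spec.total_variance)
        for k in ("expert", "landcover", "species")
    }
    sd_res = math.sqrt(spec.residual_share * spec.total_variance)
    experts = [f"E{i + 1}" for i in range(spec.n_experts)]
    a = dict(zip(experts, rng.normal(0, sd["expert"], spec.n_experts)))
    b = dict(zip(spec.landcovers, rng.normal(0, sd["landcover"], len(spec.landcovers))))
    c = dict(zip(spec.species, rng.normal(0, sd["species"], len(spec.species))))

    tm = spec.true_means.set_index(["species", "landcover", "distance_m"])[
        "true_mean"
    ]
    rows = []
    for e in experts:
        for sp in spec.species:
            for lc in spec.landcovers:
                for d in spec.distances:
                    mu = float(tm.loc[(sp, lc, d)])
                    eps = rng.normal(0, sd_res) if sd_res > 0 else 0.0
                    est = mu + a[e] + b[lc] + c[sp] + eps
                    rows.append((e, sp, lc, d, float(np.clip(est, PROB_MIN, PROB_MAX))))
    return ExpertPanel(
        data=pd.DataFrame(
            rows,
            columns=["expert", "species", "landcover", "distance_m", "probability"],
        )
    )
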