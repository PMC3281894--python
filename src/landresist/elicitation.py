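"""Aggregation of expert-opinion mobility estimates into resistance tables.

A panel of ornithologists estimates, for each species, land-cover class
and gap distance, the probability that an individual bird traverses that
distance of that land cover during its lifetime (bounded to
[0.0001, 1]).  The mean over experts is the landscape *conductivity*;
its reciprocal is the land-cover class *resistance*, so the attainable
resistance range is exactly [1, 10000].

The among-expert structure of the estimates is summarized by a crossed
random-effects variance decomposition (expert, land-cover, species, and
distance when pooling over distances), estimated by an ANOVA
(method-of-moments) estimator on the main-effect mean squares, with
negative component estimates truncated at zero and the components
reported as percentages of their total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surfaces import ResistanceTable

__all__ = [
    "DISTANCES_M",
    "ExpertPanel",
    "VarianceDecomposition",
    "mean_conductivity",
    "resistance_from_conductivity",
    "merge_equal_classes",
    "variance_components",
    "build_eo_tables",
]

#: Canonical elicitation gap distances (metres).
DISTANCES_M = (100, 200, 500, 1000, 2000, 5000, 10000)

PROB_MIN = 0.0001
PROB_MAX = 1.0

_FACTORS = ("expert", "species", "landcover", "distance_m")


@dataclass
class ExpertPanel:
    """Long-form expert traversal-probability estimates.

    ``data`` has columns expert, species, landcover, distance_m,
    probability; incomplete crossings are permitted (missing cells are
    simply absent rows) but each present probability must lie within
    [0.0001, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in (*_FACTORS, "probability") if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        p = self.data["probability"].to_numpy(float)
        if np.isnan(p).any():
            raise ValueError("panel probabilities must not be NaN")
        if (p < PROB_MIN - 1e-12).any() or (p > PROB_MAX + 1e-12).any():
            raise ValueError(
                f"probabilities must lie in [{PROB_MIN}, {PROB_MAX}]"
            )

    @property
    def experts(self) -> list:
        return sorted(self.data["expert"].unique())

    @property
    def species(self) -> list:
        return sorted(self.data["species"].unique())

    @property
    def landcovers(self) -> list:
        return sorted(self.data["landcover"].unique())

    @property
    def distances(self) -> list:
        return sorted(self.data["distance_m"].unique())

    @classmethod
    def read(cls, path) -> "ExpertPanel":
        return cls(pd.read_csv(path))

    def write(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class VarianceDecomposition:
    """Percentage of variance attributed to each random component."""

    percentages: dict[str, float]
    degenerate: bool = False
    per_distance: dict[float, "VarianceDecomposition"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.percentages.items():
            if not (0 <= p <= 100 + 1e-9):
                raise ValueError(f"component {name!r} outside [0, 100]: {p}")


def mean_conductivity(panel: ExpertPanel) -> pd.Series:
    """Mean over experts of the traversal probability, per
    (species, landcover, distance_m) combination — the landscape
    conductivity."""
    grouped = panel.data.groupby(["species", "landcover", "distance_m"])[
        "probability"
    ]
    means = grouped.mean()
    expected = pd.MultiIndex.from_product(
        [panel.species, panel.landcovers, panel.distances],
        names=["species", "landcover", "distance_m"],
    )
    missing = expected.difference(means.index)
    if len(missing):
        raise ValueError(f"no estimates for combinations: {list(missing)}")
    return means


def resistance_from_conductivity(conductivity):
    """Resistance = 1 / conductivity; maps (0, 1] onto [1, inf), and the
    permissible probability floor 0.0001 onto the 10000 ceiling."""
    c = np.asarray(conductivity, dtype=float)
    if (c <= 0).any() or (c > 1 + 1e-12).any():
        raise ValueError("conductivity must lie in (0, 1]")
    r = 1.0 / c
    return float(r) if np.isscalar(conductivity) else r


def merge_equal_classes(
    table: dict[str, float], tolerance: float = 0.0
) -> tuple[list[list[str]], dict[str, float]]:
    """Partition land-cover classes into groups of equal resistance.

    Classes whose resistances agree within relative ``tolerance`` share a
    group (exact ties by default).  Returns the groups (each sorted, in
    ascending resistance order) and a reduced table mapping each group's
    representative (its first member) to the group mean resistance.
    """
    items = sorted(table.items(), key=lambda kv: kv[1])
    groups: list[list[str]] = []
    values: list[list[float]] = []
    for cls, r in items:
        if groups and abs(r - values[-1][0]) <= tolerance * max(abs(values[-1][0]), 1e-300):
            groups[-1].append(cls)
            values[-1].append(r)
        else:
            groups.append([cls])
            values.append([r])
    groups = [sorted(g) for g in groups]
    reduced = {g[0]: float(np.mean(v)) for g, v in zip(groups, values)}
    return groups, reduced


def _anova_components(df: pd.DataFrame, factors: list[str]) -> dict[str, float]:
    """Method-of-moments variance components of an additive crossed
    random-effects model, from main-effect mean squares.

    For a balanced crossing, E[MS_F] = sigma_e^2 + r_F * sigma_F^2 with
    r_F the per-level replication; negative solutions are truncated at 0.
    """
    y = df["probability"].to_numpy(float)
    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss = {}
    dfree = {}
    repl = {}
    for f in factors:
        means = df.groupby(f)["probability"].mean()
        counts = df.groupby(f)["probability"].count()
        ss[f] = float((counts * (means - grand) ** 2).sum())
        dfree[f] = len(means) - 1
        repl[f] = float(counts.mean())
    ss_res = ss_total - sum(ss.values())
    df_res = (n - 1) - sum(dfree.values())
    if df_res <= 0 or ss_res < 0:
        ss_res = max(ss_res, 0.0)
        df_res = max(df_res, 1)
    ms_res = ss_res / df_res
    comps = {}
    for f in factors:
        if dfree[f] == 0:
            comps[f] = 0.0
            continue
        ms = ss[f] / dfree[f]
        comps[f] = max((ms - ms_res) / repl[f], 0.0)
    comps["residual"] = ms_res
    return comps


_COMPONENT_LABEL = {
    "distance_m": "distance",
    "expert": "expert",
    "landcover": "land-cover",
    "species": "species",
    "residual": "residual",
}


def variance_components(
    panel: ExpertPanel, by_distance: bool = False
) -> VarianceDecomposition:
    """Crossed random-effects variance decomposition of the panel.

    Pooling all distances yields five components (distance, expert,
    land-cover, species, residual) as percentages of total summing to
    100.  With ``by_distance`` the decomposition is additionally computed
    within each distance, dropping the distance component.
    """
    df = panel.data
    for f in ("expert", "species", "landcover"):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    pooled_factors = ["distance_m", "expert", "landcover", "species"]
    if df["distance_m"].nunique() < 2:
        pooled_factors.remove("distance_m")

    def decompose(sub: pd.DataFrame, factors: list[str]) -> VarianceDecomposition:
        if np.allclose(sub["probability"].var(ddof=0), 0.0):
            pct = {_COMPONENT_LABEL[f]: 0.0 for f in factors + ["residual"]}
            return VarianceDecomposition(percentages=pct, degenerate=True)
        comps = _anova_components(sub, factors)
        total = sum(comps.values())
        pct = {
            _COMPONENT_LABEL[f]: 100.0 * v / total for f, v in comps.items()
        }
        return VarianceDecomposition(percentages=pct)

    overall = decompose(df, pooled_factors)
    if by_distance:
        for d in panel.distances:
            sub = df[df["distance_m"] == d]
            overall.per_distance[float(d)] = decompose(
                sub, ["expert", "landcover", "species"]
            )
    return overall


def build_eo_tables(
    panel: ExpertPanel,
    distance: float,
    merge_tolerance: float | None = None,
) -> dict[str, ResistanceTable]:
    """Per-species expert-opinion resistance tables at one gap distance.

    Each land-cover class receives the reciprocal of the mean expert
    conductivity; model codes are ``<SPECIES>_EO_<distance>``.  When
    ``merge_tolerance`` is given, classes with equal resistance (within
    the relative tolerance) are reported through ``merge_equal_classes``
    but every class keeps its own entry in the returned table.
    """
    if distance not in set(panel.distances):
        raise ValueError(
            f"distance {distance} not elicited (panel has {panel.distances})"
        )
    cond = mean_conductivity(panel)
    tables = {}
    for sp in panel.species:
        mapping = {}
        for lc in panel.landcovers:
            key = (sp, lc, distance)
            if key not in cond.index:
                raise KeyError(
                    f"species {sp!r} has no estimates for {lc!r} at {distance} m"
                )
            mapping[str(lc)] = resistance_from_conductivity(cond.loc[key])
        if merge_tolerance is not None:
            merge_equal_classes(mapping, tolerance=merge_tolerance)
        code = f"{sp}_EO_{int(distance)}"
        tables[str(sp)] = ResistanceTable(model_code=code, mapping=mapping)
    return tables
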