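"""landresist: landscape resistance surfaces and effective-distance models.

A toolkit for a-priori landscape-genetic modelling: build per-species
resistance surfaces from tree-cover, habitat-suitability and
expert-opinion inputs; compute pairwise effective distances between
sampling sites by least-cost path and by circuit-theory effective
resistance; validate null models (including the grid edge effect);
compare correlated distance models with an independent-pair bootstrap;
and aggregate expert-opinion mobility estimates with variance
decomposition.
"""

from importlib import resources

from .raster import (
    Grid,
    SiteSet,
    StudyRegion,
    build_study_region,
    read_ascii_grid,
    read_sites,
    write_ascii_grid,
    write_sites,
)
from .surfaces import (
    EO_CATEGORY,
    LandCover,
    ResistanceSurface,
    ResistanceTable,
    binarize_sdm,
    classify_scattered_trees,
    generalize_tree_cover,
    habitat_surface,
    landcover_surface,
    read_resistance_tables,
    tree_surface,
    uniform_surface,
)
from .distance import (
    EdgeEffectCurve,
    PairwiseDistanceMatrix,
    WeightedGridGraph,
    build_grid_graph,
    edge_effect_experiment,
    effective_resistances,
    least_cost_distances,
    run_model_suite,
)
from .comparison import (
    BootstrapCorrelation,
    HypothesisRanking,
    bootstrap_r2,
    evaluate_ranking,
    geographic_distances,
    load_predicted_rankings,
    null_model_fit,
    sample_independent_pairs,
)
from .elicitation import (
    DISTANCES_M,
    ExpertPanel,
    VarianceDecomposition,
    build_eo_tables,
    mean_conductivity,
    merge_equal_classes,
    resistance_from_conductivity,
    variance_components,
)
from .synthetic import (
    LandscapeSpec,
    PanelSpec,
    simulate_expert_panel,
    simulate_landcover,
    simulate_sdm,
    simulate_sites,
)

__version__ = "0.1.0"


def load_reference_tables():
    """The published per-model resistance tables shipped with the package."""
    path = resources.files("landresist.data") / "resistance_tables.csv"
    return read_resistance_tables(path)
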