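"""loxshield: steric-shielding model of lipoxygenase product specificity.

Predicts the regio- and stereospecific distribution of antarafacial
oxygenation products (9R-, 11R-, 13S-HPODE) from ensembles of active-site
structure snapshots, by scoring how sterically accessible each reactive
carbon's O2 probe point is, plus utilities for structural comparison,
substrate dihedral analysis, and synthetic ground-truth ensembles.
"""

from .structure_io import (
    AtomRecord,
    Snapshot,
    TrajectoryEnsemble,
    SelectionError,
    read_structure,
    read_trajectory,
    write_ensemble_pdb,
    select_atoms,
    annotate,
    annotate_ensemble,
    write_report,
    read_report,
)
from .shielding_geometry import (
    OPEN,
    ShieldingConfig,
    PlaneFit,
    ProbeSite,
    REACTIVE_CARBONS,
    fit_pentadiene_plane,
    orient_antarafacial,
    build_probe_points,
    min_blocker_distance,
    accessibility_score,
    snapshot_accessibility,
    ensemble_accessibility,
)
from .product_model import (
    CARBON_LABELS,
    PRODUCT_LABELS,
    NO_CONTRIBUTION,
    AccessibilityProfile,
    ProductDistribution,
    ComparisonStats,
    map_stereo_labels,
    snapshot_weights,
    aggregate_trajectory,
    apply_bisallylic_penalty,
    average_replicates,
    compare_distributions,
    read_experimental_table,
    predict_distribution,
)
from .conformation import (
    DihedralSeries,
    dihedral_angle,
    dihedral_series,
    dihedral_histogram,
    series_to_csv,
    histogram_to_csv,
)
from .structure_compare import (
    Superposition,
    ClampResidueTable,
    kabsch_superpose,
    rotation_angle,
    chain_pairing,
    align_structures,
    load_clamp_table,
    clamp_table_lookup,
)
from .synthetic_scenes import (
    SceneSpec,
    build_pentadiene_template,
    build_scene,
    ground_truth_distribution,
)

__version__ = "0.1.0"


def predict_product_distribution(ensemble, config=None, penalty_mode="relative"):
    """End-to-end prediction for one annotated snapshot ensemble: per-snapshot
    accessibility -> trajectory aggregation -> bis-allylic penalty."""
    config = config or ShieldingConfig()
    profiles = ensemble_accessibility(ensemble, config)
    return predict_distribution(profiles, config.c11_penalty, penalty_mode)
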