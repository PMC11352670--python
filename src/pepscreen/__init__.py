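"""pepscreen: in silico protease digestion and bioactive peptide screening.

The toolkit mirrors a complete in silico peptide-discovery workflow:
select the most abundantly expressed annotated proteins of a tissue,
digest them with every ordered pair (or triple) of proteases from a
40-enzyme rule library, count unique 5-30 residue peptides per bioactivity
class with a pluggable multi-label predictor, and pass candidates through
a safety/stability/consensus/pose-energy filter cascade.
"""

from .cleavage import (
    CleavageRule,
    Enzyme,
    EnzymeLibrary,
    PeptideFragment,
    bundled_library,
    digest,
    find_cleavage_sites,
    length_filter,
    parse_enzyme_library,
    sequential_digest,
)
from .config import WorkflowConfig, load_config
from .filtering import (
    ConsensusPolicy,
    FilterAudit,
    PoseEnergy,
    SafetyVerdict,
    Thresholds,
    apply_safety_filters,
    consensus_bioactivity,
    filter_poses_by_energy,
    score_threshold_gate,
)
from .predictors import (
    BIOACTIVITY_CLASSES,
    BioactivityPrediction,
    BioactivityPredictor,
    CompositionHeuristicPredictor,
    SeededRandomPredictor,
    TableBackedPredictor,
    predict_bioactivity,
)
from .screening import (
    EnzymeCombination,
    ScreenConfig,
    ScreenResult,
    best_combination_per_class,
    compare_depths,
    enumerate_combinations,
    format_best_combinations,
    screen,
)
from .substrates import (
    ExpressionRecord,
    ProteinRecord,
    average_replicates,
    read_expression_table,
    select_top_expressed,
)
from .synthetic import SyntheticConfig, generate_fixture

__version__ = "0.1.0"

__all__ = [
    "BIOACTIVITY_CLASSES",
    "BioactivityPrediction",
    "BioactivityPredictor",
    "CleavageRule",
    "CompositionHeuristicPredictor",
    "ConsensusPolicy",
    "Enzyme",
    "EnzymeCombination",
    "EnzymeLibrary",
    "ExpressionRecord",
    "FilterAudit",
    "PeptideFragment",
    "PoseEnergy",
    "ProteinRecord",
    "SafetyVerdict",
    "ScreenConfig",
    "ScreenResult",
    "SeededRandomPredictor",
    "SyntheticConfig",
    "TableBackedPredictor",
    "Thresholds",
    "WorkflowConfig",
    "apply_safety_filters",
    "average_replicates",
    "best_combination_per_class",
    "bundled_library",
    "compare_depths",
    "consensus_bioactivity",
    "digest",
    "enumerate_combinations",
    "filter_poses_by_energy",
    "find_cleavage_sites",
    "format_best_combinations",
    "generate_fixture",
    "length_filter",
    "load_config",
    "parse_enzyme_library",
    "predict_bioactivity",
    "read_expression_table",
    "screen",
    "score_threshold_gate",
    "select_top_expressed",
    "sequential_digest",
]
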