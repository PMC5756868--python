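"""divesearch: behavioral annotation of central-place-forager GPS tracks and
validation of inferred search behavior against time-depth-recorder dives.

The package provides a common preprocessing pipeline (projection, temporal
regularization, movement metrics, colony/night filters), five point-wise
search annotators (first passage time, MacQueen k-means, speed–tortuosity
thresholds, a gamma/von-Mises hidden Markov model, and expectation–
maximization binary clustering), quartic-kernel density surfaces with a
spatially corrected correlation test, a gradient-boosted dive classifier,
a search-chain evaluation framework, and a synthetic trip simulator with
known latent states for end-to-end validation.
"""

from .base import TrajectoryAnnotator
from .density import (
    DensityGrid,
    DutilleulResult,
    dutilleul_correlation,
    kernel_density,
    modified_ttest,
)
from .dive_ml import (
    ConfusionMatrix,
    DiveClassifier,
    build_feature_table,
    evaluate_dive_model,
    kappa_from_confusion,
    recall_from_confusion,
    split_train_test,
)
from .dives import detect_dives, match_dives
from .embc import EMbCAnnotator, EmbcModel, embc_fit
from .evaluation import (
    EvalSummary,
    SearchChain,
    compare_methods,
    evaluate_annotation,
    extract_chains,
    kendall_tau,
    summarize,
    truth_annotation,
    write_report,
)
from .fpt import FPTAnnotator, FptProfile, fpt_classify, fpt_select_radius, fpt_values
from .hmm import HMMAnnotator, HmmModel, hmm_fit, hmm_forward_loglik, hmm_viterbi
from .io import read_config, read_dives, read_tracks, write_annotations, write_tracks
from .kmeans import KMeansAnnotator, macqueen_kmeans
from .simulate import (
    BASS_ROCK,
    GREAT_SALTEE,
    SimConfig,
    SimTruth,
    StateParams,
    simulate_colony_dataset,
    simulate_patchy_track,
    simulate_trip,
)
from .thresholds import ThresholdAnnotator
from .trajectory import (
    apply_filters,
    assign_trips,
    compute_metrics,
    interpolate_time,
    preprocess,
    project_tracks,
    rediscretize_space,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def default_annotators(random_state: int = 0) -> dict:
    """The five chain-producing annotation methods with default settings."""
    return {
        "fpt": FPTAnnotator(),
        "kmeans": KMeansAnnotator(random_state=random_state),
        "thresholds": ThresholdAnnotator(),
        "hmm": HMMAnnotator(random_state=random_state),
        "embc": EMbCAnnotator(),
    }
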