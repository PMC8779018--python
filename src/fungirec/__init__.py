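"""fungirec — post-network toolkit for citizen-science species recognition.

Building blocks for the probability-space half of a fine-grained species
recognition service: re-expressing classifier posteriors under shifted
class priors, Bayesian fusion with habitat/substrate/month metadata,
test-time-augmentation and ensemble pooling, long-tail evaluation
metrics, and a fully discrete synthetic-data generator whose exact Bayes
posteriors serve as correctness oracles.
"""

__version__ = "0.1.0"

from .core import (
    LabelSpace,
    MetadataTable,
    PosteriorMatrix,
    PriorVector,
    normalize_rows,
    validate,
)
from .evaluation import (
    EvalReport,
    evaluate,
    mean_class_accuracy,
    rank_shares,
    relative_error_reduction,
    species_split,
    topk_accuracy,
)
from .metadata_fusion import (
    FrequencyModel,
    fit_frequency_model,
    fuse,
    species_given_metadata,
)
from .prior_shift import (
    PriorShiftSpec,
    adjust_posteriors,
    adjust_to_uniform,
    estimate_class_priors,
)
from .simulator import (
    GenerativeModel,
    SyntheticDataset,
    build_model,
    exact_posterior_full,
    exact_posterior_visual,
    longtail_priors,
    sample_dataset,
    true_frequency_model,
)
from .tta import (
    CropSpec,
    PredictionStack,
    crop_pixels,
    pool_mode,
    pool_sum,
    tta_crop_specs,
)

__all__ = [
    "LabelSpace",
    "MetadataTable",
    "PosteriorMatrix",
    "PriorVector",
    "normalize_rows",
    "validate",
    "PriorShiftSpec",
    "adjust_posteriors",
    "adjust_to_uniform",
    "estimate_class_priors",
    "FrequencyModel",
    "fit_frequency_model",
    "fuse",
    "species_given_metadata",
    "CropSpec",
    "PredictionStack",
    "crop_pixels",
    "pool_mode",
    "pool_sum",
    "tta_crop_specs",
    "EvalReport",
    "evaluate",
    "topk_accuracy",
    "mean_class_accuracy",
    "rank_shares",
    "relative_error_reduction",
    "species_split",
    "GenerativeModel",
    "SyntheticDataset",
    "build_model",
    "sample_dataset",
    "longtail_priors",
    "exact_posterior_visual",
    "exact_posterior_full",
    "true_frequency_model",
]
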