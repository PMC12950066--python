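"""gaitrec: walking vs non-walking recognition from a single lower-back IMU.

Pipeline stages: synthetic data simulation, sliding-window segmentation
with per-window mean normalization, quarter-turn rotation augmentation,
class balancing by down-sampling, participant-disjoint repeated hold-out
splitting, a small 1D CNN classifier, and five-metric evaluation with
median(IQR) aggregation.
"""

from .io import (
    ActivityLabelSet,
    IMURecording,
    RecordingDialect,
    read_recordings,
    read_windows,
    resample_recording,
    write_recording,
    write_windows,
)
from .preprocess import (
    DEFAULT_ROTATIONS,
    WindowSet,
    augment,
    balance,
    binarize_labels,
    concat_windowsets,
    normalize,
    rotate90,
    rotation_matrix,
    segment,
)
from .split import SplitSpec, apportion, materialize, split_by_participant
from .synthetic import SyntheticConfig, simulate_dataset, simulate_participant
from .model import (
    CLASS_ORDER,
    CNN1D,
    ModelConfig,
    TrainedModel,
    build_cnn,
    load_model,
    predict,
    save_model,
    train,
)
from .evaluate import (
    HoldoutResult,
    MetricsReport,
    build_windows,
    class_ratio,
    confusion,
    evaluate_predictions,
    format_ratio,
    imbalance_ratio,
    median_iqr,
    metrics,
    repeated_holdout,
    select_best,
)
from .pipeline import PipelineConfig, run_experiment

__version__ = "0.1.0"
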