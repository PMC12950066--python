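"""Confusion-matrix metrics, class-ratio bookkeeping, repeated hold-out
orchestration, sensitivity-based model selection, and median(IQR)
summaries.

Walking (label 1) is the positive class for every metric.  Metrics with a
zero denominator evaluate to 0 and the report is flagged, so degenerate
all-one-class predictions never crash a repeat loop.  The interquartile
range uses the Hazen convention (linear interpolation of order statistics
at h = n p + 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, RatioError
from .io import ActivityLabelSet
from .model import ModelConfig, build_cnn, predict, train
from .preprocess import (
    DEFAULT_ROTATIONS,
    WindowSet,
    augment,
    balance,
    binarize_labels,
    concat_windowsets,
    normalize,
    rotate90,
    segment,
)
from .split import split_by_participant


@dataclass
class MetricsReport:
    """Confusion counts and the five derived metrics for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    specificity: float
    n_windows: int
    flags: tuple = ()
    role: str = ""
    channels: int = 0
    augmented: bool = False
    repeat_index: int = -1

    METRIC_NAMES = ("accuracy", "precision", "sensitivity", "f1", "specificity")


def confusion(pred, truth) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) with walking = 1 as the positive class."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return tp, fp, tn, fn


def metrics(tp: int, fp: int, tn: int, fn: int, **context) -> MetricsReport:
    """Derive accuracy, precision, sensitivity, F1 and specificity.

    Zero-denominator metrics are 0 and named in ``flags``.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("all-zero confusion counts")
    flags = []

    def safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    sensitivity = safe(tp, tp + fn, "sensitivity")
    specificity = safe(tn, tn + fp, "specificity")
    f1 = safe(2 * precision * sensitivity, precision + sensitivity, "f1")
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        specificity=specificity,
        n_windows=n,
        flags=tuple(flags),
        **context,
    )


def evaluate_predictions(pred, truth, **context) -> MetricsReport:
    return metrics(*confusion(pred, truth), **context)


def class_ratio(ws: WindowSet) -> float:
    """Non-walking : walking imbalance, returned as the r of "1:r".

    Report r rounded to 2 decimals; e.g. window counts (walking 15235,
    non-walking 131208) give 1:8.61.
    """
    n_non, n_walk = ws.class_counts()
    return imbalance_ratio(n_walk, n_non)


def imbalance_ratio(n_walking: int, n_nonwalking: int) -> float:
    if n_walking == 0:
        raise RatioError("class ratio undefined: no walking windows")
    return n_nonwalking / n_walking


def format_ratio(r: float) -> str:
    return f"1:{r:.2f}"


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range, Hazen quantile convention.

    Hazen places the p-quantile at rank h = n p + 1/2 with linear
    interpolation between order statistics, e.g. the IQR of
    [0.9, 0.92, 0.94, 0.96, 0.98] is 0.965 - 0.915 = 0.05.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median_iqr of empty sequence")
    q25, q75 = np.quantile(values, [0.25, 0.75], method="hazen")
    return float(np.median(values)), float(q75 - q25)


# ---------------------------------------------------------------------------
# repeated hold-out orchestration


def build_windows(
    recordings,
    als: ActivityLabelSet | None = None,
    channels: int = 6,
    rotations=None,
    window_len: int = 200,
    overlap: float = 0.5,
    balance_seed: int | None = None,
) -> WindowSet:
    """Recording collection -> normalized WindowSet.

    Stage order mirrors the training pipeline: (optional) recording-level
    rotation augmentation, then segmentation, then per-window
    normalization, then (optional) class balancing.  Balancing must only
    be requested for training/validation pools; test pools stay untouched.
    """
    als = als or ActivityLabelSet()
    recs = list(recordings)
    if rotations:
        originals = list(recs)
        for axis, turns in rotations:
            recs.extend(rotate90(r, axis, turns) for r in originals)
    sets = []
    for rec in recs:
        ws = segment(rec, binarize_labels(rec, als), window_len, overlap)
        if ws.n_windows:
            sets.append(ws)
    ws = concat_windowsets(sets)
    if channels == 3:
        ws = ws.acc_only()
    ws = normalize(ws)
    if balance_seed is not None:
        ws = balance(ws, balance_seed)
    return ws


@dataclass
class HoldoutResult:
    """Per-repeat reports, summaries and (optionally) trained models for
    one grid cell (channels x augmentation)."""

    channels: int
    augmented: bool
    val_reports: list = field(default_factory=list)
    test_reports: list = field(default_factory=list)
    models: list = field(default_factory=list)

    def summary(self) -> dict:
        out = {}
        for role, reports in (("val", self.val_reports), ("test", self.test_reports)):
            for name in MetricsReport.METRIC_NAMES:
                med, iqr = median_iqr([getattr(r, name) for r in reports])
                out[f"{role}_{name}_median"] = med
                out[f"{role}_{name}_iqr"] = iqr
        return out


def repeated_holdout(
    recordings,
    repeats: int = 10,
    grid=((6, False), (6, True), (3, False), (3, True)),
    base_seed: int = 0,
    model_cfg: ModelConfig | None = None,
    als: ActivityLabelSet | None = None,
    rotations=DEFAULT_ROTATIONS,
    fractions=(0.55, 0.25, 0.20),
    window_len: int = 200,
    overlap: float = 0.5,
    keep_models: bool = False,
) -> dict:
    """Subject-wise repeated hold-out over a (channels x augmentation) grid.

    Per repeat and grid cell: split by participant, rotate-augment the
    train/val recordings (DA cells only), segment, normalize, balance the
    train/val pools, train, and evaluate on the untouched test pool.
    Returns ``{(channels, augmented): HoldoutResult}``; summaries report
    median and IQR of each metric.
    """
    if repeats < 1:
        raise ConfigError("repeats must be >= 1")
    recordings = list(recordings)
    ids = [r.participant_id for r in recordings]
    if len(ids) < 3:
        raise ConfigError("need >= 3 participants")
    base = model_cfg or ModelConfig()
    results = {
        (ch, da): HoldoutResult(channels=ch, augmented=da) for ch, da in grid
    }
    # Segment each participant once and reuse across repeats and grid
    # cells.  Rotation is a per-sample linear map, so rotating windows
    # equals rotating the recording before segmentation (the stage order
    # of the training pipeline); augmentation is applied window-level.
    als = als or ActivityLabelSet()
    seg_cache = {
        rec.participant_id: segment(
            rec, binarize_labels(rec, als), window_len, overlap
        )
        for rec in recordings
    }

    def pool(id_set, channels, augmented, balance_seed=None):
        ws = concat_windowsets([seg_cache[pid] for pid in sorted(id_set)])
        if augmented:
            ws = augment(ws, rotations)
        if channels == 3:
            ws = ws.acc_only()
        ws = normalize(ws)
        if balance_seed is not None:
            ws = balance(ws, balance_seed)
        return ws

    for rep in range(repeats):
        # one seed per repeat drives split, balancing and training
        rep_seed = base_seed + 1000 * rep
        sp = split_by_participant(ids, fractions, seed=rep_seed, repeat_index=rep)
        for ch, da in grid:
            tr = pool(sp.train_ids, ch, da, balance_seed=rep_seed + 1)
            va = pool(sp.val_ids, ch, da, balance_seed=rep_seed + 2)
            te = pool(sp.test_ids, ch, False)
            cfg = ModelConfig(**{**_cfg_dict(base), "n_channels": ch, "seed": rep_seed + 3})
            tm = train(build_cnn(cfg), tr, va, cfg)
            res = results[(ch, da)]
            for role, ws, reports in (
                ("val", va, res.val_reports),
                ("test", te, res.test_reports),
            ):
                _, hard = predict(tm, ws)
                reports.append(
                    evaluate_predictions(
                        hard, ws.labels, role=role, channels=ch,
                        augmented=da, repeat_index=rep,
                    )
                )
            if keep_models:
                res.models.append(tm)
    return results


def _cfg_dict(cfg: ModelConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def select_best(candidates):
    """Pick the model with the highest validation sensitivity.

    ``candidates`` is a sequence of (MetricsReport, model) pairs from the
    validation pool.  Ties break to higher F1, then to the lower repeat
    index (earlier candidate).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate models")
    best_i = min(
        range(len(candidates)),
        key=lambda i: (
            -candidates[i][0].sensitivity,
            -candidates[i][0].f1,
            candidates[i][0].repeat_index if candidates[i][0].repeat_index >= 0 else i,
            i,
        ),
    )
    return candidates[best_i][1]
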