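"""Signal preprocessing: label binarization, sliding-window segmentation,
per-window mean normalization, quarter-turn rotation augmentation, and
majority-class down-sampling.

The unit of classification is a fixed-length window (default 200 samples,
2 s at 100 Hz) with 50% overlap between consecutive windows.  Each window
carries a single binary label (1 = walking, 0 = non-walking) assigned by
majority vote over its per-sample labels, with ties resolved to
non-walking so that walking sensitivity is never inflated by ambiguous
windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import BalanceError, DataError, StateError
from .io import ActivityLabelSet, IMURecording

#: Right-handed +90-degree rotation matrices about the sensor axes,
#: acting on column vectors (v' = R v).
_QUARTER_TURN = {
    "x": np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
    "y": np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]], dtype=float),
    "z": np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float),
}

#: Default augmentation set: one quarter-turn about each sensor axis,
#: emulating major sensor placement shifts.
DEFAULT_ROTATIONS = (("x", 1), ("y", 1), ("z", 1))


@dataclass
class WindowSet:
    """Segmented fixed-length windows with binary labels and provenance.

    Fields
    ------
    windows : ndarray (n, W, C)
    labels : ndarray int8, 1 = walking, 0 = non-walking
    participant_ids : ndarray of str, provenance of every window
    augmented_from : ndarray of str, rotation tag per window
        ("" for originals, e.g. "x+1" for a copy rotated one quarter-turn
        about x).
    """

    windows: np.ndarray
    labels: np.ndarray
    participant_ids: np.ndarray
    window_len_samples: int = 200
    overlap_fraction: float = 0.5
    normalized: bool = False
    augmented_from: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.participant_ids = np.asarray(self.participant_ids, dtype=str)
        if self.augmented_from is None:
            self.augmented_from = np.full(len(self.labels), "", dtype="<U8")
        else:
            self.augmented_from = np.asarray(self.augmented_from, dtype=str)
        n = self.windows.shape[0]
        if not (
            len(self.labels) == len(self.participant_ids)
            == len(self.augmented_from) == n
        ):
            raise DataError("window/label/provenance lengths disagree")
        if self.windows.ndim != 3:
            raise DataError("windows must be a (n, W, C) array")
        if self.window_len_samples < 2:
            raise DataError("window_len_samples must be >= 2")
        if not 0 <= self.overlap_fraction < 1:
            raise DataError("overlap_fraction must be in [0, 1)")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def class_counts(self) -> tuple[int, int]:
        """(n_nonwalking, n_walking)."""
        walking = int(np.sum(self.labels == 1))
        return self.n_windows - walking, walking

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            windows=self.windows[idx],
            labels=self.labels[idx],
            participant_ids=self.participant_ids[idx],
            window_len_samples=self.window_len_samples,
            overlap_fraction=self.overlap_fraction,
            normalized=self.normalized,
            augmented_from=self.augmented_from[idx],
        )

    def acc_only(self) -> "WindowSet":
        """Drop gyroscope channels, yielding a 3-channel WindowSet."""
        if self.n_channels == 3:
            return self
        out = self.subset(np.arange(self.n_windows))
        out.windows = out.windows[:, :, :3].copy()
        return out


def concat_windowsets(sets: list[WindowSet]) -> WindowSet:
    """Concatenate WindowSets with identical geometry and state."""
    sets = [s for s in sets if s.n_windows > 0]
    if not sets:
        raise DataError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if (
            s.window_len_samples != first.window_len_samples
            or s.overlap_fraction != first.overlap_fraction
            or s.normalized != first.normalized
            or s.n_channels != first.n_channels
        ):
            raise DataError("WindowSets have incompatible geometry or state")
    return WindowSet(
        windows=np.concatenate([s.windows for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        participant_ids=np.concatenate([s.participant_ids for s in sets]),
        window_len_samples=first.window_len_samples,
        overlap_fraction=first.overlap_fraction,
        normalized=first.normalized,
        augmented_from=np.concatenate([s.augmented_from for s in sets]),
    )


def binarize_labels(rec: IMURecording, als: ActivityLabelSet | None = None) -> np.ndarray:
    """Map per-sample activity strings to binary walking labels.

    Any label in ``als.walking_labels`` maps to 1; every other label
    (sitting, standing, shuffling, stairs, unknown strings, ...) maps to 0.
    """
    als = als or ActivityLabelSet()
    return np.isin(rec.labels, list(als.walking_labels)).astype(np.int8)


def segment(
    rec: IMURecording,
    binary_labels: np.ndarray,
    window_len: int = 200,
    overlap: float = 0.5,
) -> WindowSet:
    """Cut a recording into overlapping fixed-length windows.

    Window starts advance by ``step = round(window_len * (1 - overlap))``
    samples; trailing samples that do not fill a window are discarded.
    The window count is ``floor((T - window_len) / step) + 1``.
    """
    binary_labels = np.asarray(binary_labels, dtype=np.int8)
    if len(binary_labels) != rec.n_samples:
        raise DataError("binary_labels length must equal recording length")
    step = int(round(window_len * (1.0 - overlap)))
    if step < 1:
        raise DataError("overlap too large: step would be < 1 sample")
    T = rec.n_samples
    if T < window_len:
        warnings.warn(
            f"recording {rec.participant_id}: {T} samples < window length "
            f"{window_len}; produced 0 windows",
            stacklevel=2,
        )
        return WindowSet(
            windows=np.empty((0, window_len, rec.n_channels), dtype=np.float32),
            labels=np.empty(0, dtype=np.int8),
            participant_ids=np.empty(0, dtype=str),
            window_len_samples=window_len,
            overlap_fraction=overlap,
        )
    n = (T - window_len) // step + 1
    starts = np.arange(n) * step
    sw = np.lib.stride_tricks.sliding_window_view(rec.samples, window_len, axis=0)
    windows = sw[starts].transpose(0, 2, 1)
    lw = np.lib.stride_tricks.sliding_window_view(binary_labels, window_len)
    walking_frac = lw[starts].mean(axis=1)
    # majority vote; exact tie -> non-walking
    labels = (walking_frac > 0.5).astype(np.int8)
    return WindowSet(
        windows=windows,
        labels=labels,
        participant_ids=np.full(n, rec.participant_id, dtype="<U32"),
        window_len_samples=window_len,
        overlap_fraction=overlap,
    )


def normalize(ws: WindowSet) -> WindowSet:
    """Subtract each window's per-axis mean (the only normalization in the
    pipeline; units are otherwise taken as-is).  Raises if applied twice."""
    if ws.normalized:
        raise StateError("WindowSet is already normalized")
    out = ws.subset(np.arange(ws.n_windows))
    if out.n_windows:
        out.windows = out.windows - out.windows.mean(axis=1, keepdims=True)
    out.normalized = True
    return out


def rotation_matrix(axis: str, quarter_turns: int) -> np.ndarray:
    """Right-handed rotation by ``quarter_turns`` x 90 degrees about a
    sensor axis."""
    if axis not in _QUARTER_TURN:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}")
    if not float(quarter_turns).is_integer():
        raise ValueError("quarter_turns must be an integer")
    return np.linalg.matrix_power(_QUARTER_TURN[axis], int(quarter_turns) % 4)


def rotate90(obj, axis: str, quarter_turns: int):
    """Rotate the sensor frame by quarter-turns about one of its axes.

    The same 3x3 rotation is applied sample-wise to the accelerometer
    triad and, when present, to the gyroscope triad — a rigid sensor
    placement shift.  Per-sample triad norms are preserved and labels are
    unchanged.  Accepts an :class:`IMURecording` or a :class:`WindowSet`
    and returns the same type.
    """
    R = rotation_matrix(axis, quarter_turns)

    def apply(arr: np.ndarray) -> np.ndarray:
        out = arr.copy()
        out[..., 0:3] = arr[..., 0:3] @ R.T
        if arr.shape[-1] == 6:
            out[..., 3:6] = arr[..., 3:6] @ R.T
        return out

    if isinstance(obj, IMURecording):
        return IMURecording(
            participant_id=obj.participant_id,
            sampling_rate_hz=obj.sampling_rate_hz,
            samples=apply(obj.samples),
            labels=obj.labels.copy(),
            source=f"{obj.source} (rotated {axis}{quarter_turns:+d})",
        )
    if isinstance(obj, WindowSet):
        out = obj.subset(np.arange(obj.n_windows))
        out.windows = apply(obj.windows)
        return out
    raise TypeError(f"cannot rotate object of type {type(obj).__name__}")


def augment(ws: WindowSet, rotations=DEFAULT_ROTATIONS) -> WindowSet:
    """Append one rotated copy of every window per listed rotation.

    Output size is ``n * (1 + len(rotations))``.  Rotated copies inherit
    label and participant ID and carry an ``augmented_from`` tag such as
    "y+1".  An empty rotation list returns the input unchanged.
    """
    rotations = list(rotations)
    if not rotations:
        return ws
    parts = [ws]
    for axis, turns in rotations:
        rot = rotate90(ws, axis, turns)
        rot.augmented_from = np.full(ws.n_windows, f"{axis}{int(turns):+d}", dtype="<U8")
        parts.append(rot)
    return concat_windowsets(parts)


def balance(ws: WindowSet, seed: int) -> WindowSet:
    """Down-sample the majority class to the minority count.

    The minority class is untouched; majority windows are dropped at
    random without replacement (seeded), so the output is always a
    multiset subset of the input with equal class counts.
    """
    n_non, n_walk = ws.class_counts()
    if n_non == 0 or n_walk == 0:
        raise BalanceError(
            f"both classes required to balance (non-walking={n_non}, "
            f"walking={n_walk})"
        )
    rng = np.random.default_rng(seed)
    minority = 1 if n_walk <= n_non else 0
    n_keep = min(n_walk, n_non)
    maj_idx = np.flatnonzero(ws.labels != minority)
    keep_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(ws.labels == minority), keep_maj]))
    return ws.subset(keep)
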