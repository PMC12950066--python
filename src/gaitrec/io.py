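"""Reading and writing labeled IMU recordings and window containers.

A recording lives on disk as UTF-8 delimited text with a header row and an
optional ``# sampling_rate_hz: <value>`` comment line before the header.
Required columns: a participant-ID column, a per-sample activity-label
column, and either three (``ax, ay, az``) or six (``ax..az, gx..gz``)
signal columns.  Acceleration is in m/s^2, angular velocity in deg/s.

Window containers are single ``.npz`` files holding the window array, the
binary labels, the per-window participant IDs and a JSON metadata block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, FormatError

ACC_COLUMNS = ("ax", "ay", "az")
GYRO_COLUMNS = ("gx", "gy", "gz")


@dataclass
class RecordingDialect:
    """Column-naming convention of a recording file."""

    participant_col: str = "participant_id"
    label_col: str = "label"
    acc_cols: tuple[str, str, str] = ACC_COLUMNS
    gyro_cols: tuple[str, str, str] = GYRO_COLUMNS


@dataclass
class IMURecording:
    """One participant's continuous multi-channel inertial signal.

    Parameters
    ----------
    participant_id : str
        Unique participant identifier.
    sampling_rate_hz : float
        Nominal sampling rate; the classifier is trained at 100 Hz.
    samples : ndarray of shape (T, C), C in {3, 6}
        Columns ordered ``(ax, ay, az[, gx, gy, gz])``; acceleration in
        m/s^2, angular velocity in deg/s.
    labels : ndarray of str, length T
        Per-sample activity label (e.g. "walking", "sitting").
    source : str
        Free-text provenance.
    """

    participant_id: str
    sampling_rate_hz: float
    samples: np.ndarray
    labels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.samples.ndim != 2 or self.samples.shape[1] not in (3, 6):
            raise DataError(
                f"samples must be T x C with C in {{3, 6}}, got shape "
                f"{self.samples.shape}"
            )
        if self.labels.shape[0] != self.samples.shape[0]:
            raise DataError(
                f"{self.labels.shape[0]} labels for {self.samples.shape[0]} "
                "sample rows"
            )
        if not self.sampling_rate_hz > 0:
            raise DataError("sampling_rate_hz must be positive")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise DataError(f"non-finite sample at row {row}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class ActivityLabelSet:
    """Which activity labels count as walking; everything else is
    non-walking (including e.g. shuffling, stairs, walking-with-transitions
    in the source annotation scheme)."""

    walking_labels: frozenset = field(
        default_factory=lambda: frozenset({"walking"})
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "walking_labels", frozenset(self.walking_labels))
        if not self.walking_labels:
            raise ConfigError("walking_labels must be non-empty")


def _read_sidecar_rate(path) -> float | None:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "sampling_rate_hz":
                return float(val)
    return None


def read_recordings(
    path,
    dialect: RecordingDialect | None = None,
    sampling_rate_hz: float | None = None,
) -> list[IMURecording]:
    """Read a delimited-text recording file into one
    :class:`IMURecording` per distinct participant, preserving row order.

    The channel count (3 or 6) is inferred from which signal columns are
    present.  The sampling rate is taken from a ``# sampling_rate_hz:``
    header comment unless supplied explicitly.
    """
    dialect = dialect or RecordingDialect()
    header_rate = _read_sidecar_rate(path)
    rate = sampling_rate_hz if sampling_rate_hz is not None else header_rate
    if rate is None:
        raise FormatError(
            "sampling rate not found: supply sampling_rate_hz or add a "
            "'# sampling_rate_hz: <value>' header comment"
        )
    df = pd.read_csv(path, comment="#")
    for col in (dialect.participant_col, dialect.label_col, *dialect.acc_cols):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}'")
    have_gyro = [c for c in dialect.gyro_cols if c in df.columns]
    if have_gyro and len(have_gyro) != 3:
        missing = set(dialect.gyro_cols) - set(have_gyro)
        raise FormatError(
            f"partial gyroscope triad: missing column(s) {sorted(missing)}"
        )
    signal_cols = list(dialect.acc_cols) + (list(dialect.gyro_cols) if have_gyro else [])
    sig = df[signal_cols]
    # A row missing only some channels would silently change C mid-file.
    per_row_missing = sig.isna().sum(axis=1)
    if ((per_row_missing > 0) & (per_row_missing < len(signal_cols))).any():
        raise FormatError("mixed channel counts across rows")
    samples = sig.to_numpy(dtype=float)
    bad = ~np.isfinite(samples)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise DataError(f"non-finite sample at row {row}")

    recordings = []
    for pid in pd.unique(df[dialect.participant_col]):
        mask = (df[dialect.participant_col] == pid).to_numpy()
        recordings.append(
            IMURecording(
                participant_id=str(pid),
                sampling_rate_hz=float(rate),
                samples=samples[mask],
                labels=df[dialect.label_col].to_numpy(dtype=str)[mask],
                source=str(path),
            )
        )
    return recordings


def write_recording(rec: IMURecording, path) -> None:
    """Write one recording in the dialect that :func:`read_recordings`
    reads, with the sampling rate as a header comment."""
    cols = list(ACC_COLUMNS) + (list(GYRO_COLUMNS) if rec.n_channels == 6 else [])
    df = pd.DataFrame(rec.samples, columns=cols)
    df.insert(0, "participant_id", rec.participant_id)
    df.insert(1, "label", rec.labels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sampling_rate_hz: {rec.sampling_rate_hz}\n")
        df.to_csv(fh, index=False)


def resample_recording(rec: IMURecording, target_hz: float) -> IMURecording:
    """Linearly resample a recording to ``target_hz``.

    Signals are interpolated channel-wise; labels are carried over from the
    nearest original sample.  Recordings captured at rates other than the
    model's training rate must pass through this before segmentation.
    """
    if target_hz <= 0:
        raise DataError("target_hz must be positive")
    if np.isclose(target_hz, rec.sampling_rate_hz):
        return rec
    t_old = np.arange(rec.n_samples) / rec.sampling_rate_hz
    duration = rec.n_samples / rec.sampling_rate_hz
    t_new = np.arange(0.0, duration, 1.0 / target_hz)
    t_new = t_new[t_new <= t_old[-1]]
    samples = np.column_stack(
        [np.interp(t_new, t_old, rec.samples[:, c]) for c in range(rec.n_channels)]
    )
    nearest = np.clip(
        np.round(t_new * rec.sampling_rate_hz).astype(int), 0, rec.n_samples - 1
    )
    return IMURecording(
        participant_id=rec.participant_id,
        sampling_rate_hz=target_hz,
        samples=samples,
        labels=rec.labels[nearest],
        source=f"{rec.source} (resampled {rec.sampling_rate_hz}->{target_hz} Hz)",
    )


def write_windows(ws, path) -> None:
    """Serialize a WindowSet to a single ``.npz`` container.

    Round-trip with :func:`read_windows` is bit-exact for every field.
    """
    meta = {
        "window_len_samples": int(ws.window_len_samples),
        "overlap_fraction": float(ws.overlap_fraction),
        "normalized": bool(ws.normalized),
        "n_channels": int(ws.windows.shape[2]) if ws.n_windows else 0,
    }
    np.savez(
        path,
        windows=ws.windows,
        labels=ws.labels,
        participant_ids=np.asarray(ws.participant_ids, dtype=str),
        augmented_from=np.asarray(ws.augmented_from, dtype=str),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def read_windows(path):
    """Load a WindowSet written by :func:`write_windows`."""
    from .preprocess import WindowSet

    try:
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(bytes(npz["meta"]).decode())
            return WindowSet(
                windows=npz["windows"],
                labels=npz["labels"],
                participant_ids=npz["participant_ids"].astype(str),
                window_len_samples=meta["window_len_samples"],
                overlap_fraction=meta["overlap_fraction"],
                normalized=meta["normalized"],
                augmented_from=npz["augmented_from"].astype(str),
            )
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"corrupted window container {path}: {exc}") from exc
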