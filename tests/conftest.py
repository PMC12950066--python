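import numpy as np
import pytest

from gaitrec import IMURecording, SyntheticConfig, WindowSet, simulate_dataset


def make_recording(
    labels, participant_id="P01", n_channels=6, rate=100.0, rng_seed=0
):
    """Small recording with one sample per label entry."""
    rng = np.random.default_rng(rng_seed)
    labels = np.asarray(labels, dtype=str)
    samples = rng.normal(0.0, 1.0, size=(len(labels), n_channels))
    samples[:, 2] += 9.81
    return IMURecording(
        participant_id=participant_id,
        sampling_rate_hz=rate,
        samples=samples,
        labels=labels,
        source="test",
    )


def make_windowset(n=9, W=200, C=6, walking=None, seed=0, normalized=False):
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=np.int8)
    if walking:
        labels[:walking] = 1
    return WindowSet(
        windows=rng.normal(size=(n, W, C)),
        labels=labels,
        participant_ids=np.array([f"P{i % 3:02d}" for i in range(n)]),
        window_len_samples=W,
        normalized=normalized,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six participants, five minutes each: enough for every pipeline
    stage while staying fast."""
    cfg = SyntheticConfig(n_participants=6, total_duration_s=300.0, seed=42)
    return simulate_dataset(cfg)
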