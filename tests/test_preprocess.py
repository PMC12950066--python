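import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitrec import (
    ActivityLabelSet,
    augment,
    balance,
    binarize_labels,
    normalize,
    rotate90,
    rotation_matrix,
    segment,
)
from gaitrec.exceptions import BalanceError, StateError

from conftest import make_recording, make_windowset

FREE_LIVING_LABELS = [
    "walking", "walking with transitions", "shuffling", "standing", "sitting",
    "transition", "leaning", "jumping", "dynamic", "static", "lying", "shaking",
    "picking", "kneeling", "stair ascending", "descending",
]


class TestBinarize:
    def test_basic(self):
        rec = make_recording(["walking", "sitting", "walking"])
        assert list(binarize_labels(rec)) == [1, 0, 1]

    def test_only_walking_label_maps_to_one(self):
        """Of the 16 source activity labels only plain "walking" is the
        positive class; near-walking activities stay non-walking."""
        rec = make_recording(FREE_LIVING_LABELS)
        out = binarize_labels(rec, ActivityLabelSet())
        assert out.sum() == 1 and out[0] == 1

    def test_no_walking(self):
        rec = make_recording(["sitting"] * 5)
        assert binarize_labels(rec).sum() == 0

    def test_custom_walking_set(self):
        rec = make_recording(["walking", "shuffling", "lying"])
        als = ActivityLabelSet({"walking", "shuffling"})
        assert list(binarize_labels(rec, als)) == [1, 1, 0]


def brute_force_count(T, W, step):
    return sum(1 for s in range(T) if s % step == 0 and s + W <= T)


class TestSegment:
    def test_nine_windows_from_1000(self):
        rec = make_recording(["sitting"] * 1000)
        ws = segment(rec, binarize_labels(rec), 200, 0.5)
        assert ws.n_windows == 9

    def test_exactly_one_window(self):
        rec = make_recording(["sitting"] * 200)
        assert segment(rec, binarize_labels(rec), 200, 0.5).n_windows == 1

    def test_tie_goes_to_nonwalking(self):
        labels = ["walking"] * 100 + ["sitting"] * 100
        rec = make_recording(labels)
        ws = segment(rec, binarize_labels(rec), 200, 0.5)
        assert ws.labels[0] == 0

    def test_majority_walking(self):
        labels = ["walking"] * 101 + ["sitting"] * 99
        rec = make_recording(labels)
        assert segment(rec, binarize_labels(rec), 200, 0.5).labels[0] == 1

    def test_short_recording_warns_and_is_empty(self):
        rec = make_recording(["sitting"] * 50)
        with pytest.warns(UserWarning, match="0 windows"):
            ws = segment(rec, binarize_labels(rec), 200, 0.5)
        assert ws.n_windows == 0

    def test_window_content_matches_source(self):
        rec = make_recording(["sitting"] * 300)
        ws = segment(rec, binarize_labels(rec), 200, 0.5)
        np.testing.assert_array_equal(ws.windows[1], rec.samples[100:300])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        T=st.integers(2, 600),
        W=st.integers(2, 250),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_count_matches_enumeration(self, T, W, overlap):
        step = int(round(W * (1 - overlap)))
        if step < 1 or W > T:
            return
        rec = make_recording(["sitting"] * T, n_channels=3)
        ws = segment(rec, binarize_labels(rec), W, overlap)
        assert ws.n_windows == brute_force_count(T, W, step)


class TestNormalize:
    def test_constant_axis_becomes_zero(self):
        ws = make_windowset(n=2, W=10, C=3)
        ws.windows[:, :, 1] = 7.5
        out = normalize(ws)
        assert np.abs(out.windows[:, :, 1]).max() == 0.0

    def test_zero_mean_per_axis(self):
        out = normalize(make_windowset(n=5, W=50, C=6))
        assert np.abs(out.windows.mean(axis=1)).max() < 1e-9

    def test_value_idempotent(self):
        ws = make_windowset(n=3, W=20, C=3)
        once = normalize(ws)
        again = once.subset(np.arange(once.n_windows))
        again.normalized = False
        np.testing.assert_allclose(normalize(again).windows, once.windows, atol=1e-12)

    def test_not_interchangeable_with_segmentation(self):
        """Per-window normalization after segmentation differs from
        whole-recording centering before it: the stage order matters."""
        rec = make_recording(["sitting"] * 400, n_channels=3, rng_seed=5)
        rec.samples[:, 0] += np.linspace(0, 10, 400)  # slow drift
        ws_then_norm = normalize(segment(rec, binarize_labels(rec), 200, 0.5))
        centered = rec.samples - rec.samples.mean(axis=0)
        rec_centered = make_recording(["sitting"] * 400, n_channels=3)
        rec_centered.samples = centered
        norm_then_ws = segment(rec_centered, binarize_labels(rec_centered), 200, 0.5)
        assert not np.allclose(ws_then_norm.windows, norm_then_ws.windows)

    def test_double_normalize_raises(self):
        once = normalize(make_windowset())
        with pytest.raises(StateError):
            normalize(once)

    def test_labels_and_provenance_untouched(self):
        ws = make_windowset(n=4, walking=2)
        out = normalize(ws)
        np.testing.assert_array_equal(out.labels, ws.labels)
        np.testing.assert_array_equal(out.participant_ids, ws.participant_ids)


class TestRotate90:
    def test_zero_turns_is_identity(self):
        ws = make_windowset()
        np.testing.assert_array_equal(rotate90(ws, "z", 0).windows, ws.windows)

    def test_quarter_turn_about_x(self):
        rec = make_recording(["s"], n_channels=3)
        rec.samples[0] = [0.0, 0.0, 1.0]
        out = rotate90(rec, "x", 1)
        np.testing.assert_allclose(out.samples[0], [0.0, -1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("axis", ["x", "y", "z"])
    def test_four_turns_identity(self, axis):
        ws = make_windowset(C=6)
        out = rotate90(ws, axis, 4)
        np.testing.assert_allclose(out.windows, ws.windows, atol=1e-12)

    @pytest.mark.parametrize("axis", ["x", "y", "z"])
    def test_norm_preserved_and_invertible(self, axis):
        ws = make_windowset(n=4, W=30, C=6, seed=3)
        out = rotate90(ws, axis, 1)
        for sl in (slice(0, 3), slice(3, 6)):
            np.testing.assert_allclose(
                np.linalg.norm(out.windows[..., sl], axis=-1),
                np.linalg.norm(ws.windows[..., sl], axis=-1),
                atol=1e-9,
            )
        back = rotate90(out, axis, -1)
        np.testing.assert_allclose(back.windows, ws.windows, atol=1e-9)

    def test_gyro_rotated_identically(self):
        rec = make_recording(["s"], n_channels=6)
        rec.samples[0] = [0, 0, 1.0, 0, 0, 2.0]
        out = rotate90(rec, "x", 1)
        np.testing.assert_allclose(out.samples[0], [0, -1, 0, 0, -2, 0], atol=1e-12)

    def test_non_integer_turns_rejected(self):
        with pytest.raises(ValueError):
            rotation_matrix("x", 1.5)

    def test_labels_unchanged(self):
        rec = make_recording(["walking", "sitting"])
        assert list(rotate90(rec, "y", 1).labels) == ["walking", "sitting"]


class TestAugment:
    def test_cardinality(self):
        ws = make_windowset(n=10, walking=3)
        out = augment(ws, [("x", 1), ("y", 1), ("z", 1)])
        assert out.n_windows == 40

    def test_empty_rotation_list_is_identity(self):
        ws = make_windowset(n=5)
        assert augment(ws, []) is ws

    def test_labels_and_ids_inherited(self):
        ws = make_windowset(n=6, walking=2)
        out = augment(ws, [("z", 1)])
        np.testing.assert_array_equal(out.labels[:6], out.labels[6:])
        np.testing.assert_array_equal(out.participant_ids[:6], out.participant_ids[6:])

    def test_augmented_tags(self):
        out = augment(make_windowset(n=2), [("y", 1)])
        assert list(out.augmented_from) == ["", "", "y+1", "y+1"]


class TestBalance:
    def test_downsample_to_minority(self):
        ws = make_windowset(n=13, walking=3, seed=1)
        out = balance(ws, seed=0)
        assert out.class_counts() == (3, 3)

    def test_retained_majority_is_subset(self):
        ws = make_windowset(n=13, walking=3, seed=1)
        out = balance(ws, seed=0)
        src = {w.tobytes() for w in ws.windows}
        assert all(w.tobytes() in src for w in out.windows)

    def test_already_balanced_unchanged_counts(self):
        ws = make_windowset(n=8, walking=4)
        out = balance(ws, seed=5)
        assert out.n_windows == 8 and out.class_counts() == (4, 4)

    def test_one_class_absent(self):
        with pytest.raises(BalanceError):
            balance(make_windowset(n=5, walking=0), seed=0)

    def test_seeded_determinism(self):
        ws = make_windowset(n=20, walking=5, seed=2)
        a, b = balance(ws, seed=9), balance(ws, seed=9)
        np.testing.assert_array_equal(a.windows, b.windows)
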