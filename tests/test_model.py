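import numpy as np
import pytest

import gaitrec.model as M
from gaitrec import ModelConfig, WindowSet, build_cnn, load_model, predict, save_model, train
from gaitrec.exceptions import ConfigError, DataError, StateError

SMALL = dict(window_len=40, kernel_len=5, n_filters=8, dense_units=8, pool_len=2)


def small_cfg(**kw):
    return ModelConfig(**{**SMALL, "n_channels": 3, "seed": 0, **kw})


def separable_windows(n_per_class=100, W=40, C=3, seed=0, normalized=True):
    """High-amplitude periodic windows (walking) vs near-flat noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(W) / 100.0
    walk = np.stack(
        [
            np.stack(
                [3.0 * np.sin(2 * np.pi * 1.8 * 100 * t / 100 + rng.uniform(0, 6))
                 + 0.1 * rng.normal(size=W) for _ in range(C)],
                axis=1,
            )
            for _ in range(n_per_class)
        ]
    )
    flat = rng.normal(0, 0.1, size=(n_per_class, W, C))
    X = np.concatenate([walk, flat])
    X = X - X.mean(axis=1, keepdims=True)
    y = np.concatenate([np.ones(n_per_class), np.zeros(n_per_class)]).astype(np.int8)
    return WindowSet(
        windows=X,
        labels=y,
        participant_ids=np.full(2 * n_per_class, "P00"),
        window_len_samples=W,
        normalized=True,
    )


class TestBuild:
    def test_softmax_rows_sum_to_one(self):
        net = build_cnn(small_cfg())
        x = np.random.default_rng(1).normal(size=(7, 40, 3))
        probs, _ = net.forward(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (7, 2)

    def test_channel_count_changes_first_layer_only(self):
        p6 = build_cnn(small_cfg(n_channels=6)).n_parameters
        p3 = build_cnn(small_cfg(n_channels=3)).n_parameters
        assert p6 - p3 == 8 * 5 * 3  # n_filters * kernel_len * extra channels

    def test_seeded_init_identical(self):
        a, b = build_cnn(small_cfg(seed=5)), build_cnn(small_cfg(seed=5))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_channels=4),
            dict(dropout_rate=1.0),
            dict(batch_size=0),
            dict(kernel_len=41),
            dict(kernel_len=6),
            dict(learning_rate=0.0),
        ],
    )
    def test_invalid_config(self, kw):
        with pytest.raises(ConfigError):
            small_cfg(**kw)


class TestTrain:
    def test_learns_separable_task(self):
        """Smoke oracle: any competent classifier separates periodic from
        flat windows almost perfectly."""
        ws = separable_windows(n_per_class=200)
        val = separable_windows(n_per_class=50, seed=1)
        cfg = small_cfg(max_epochs=8)
        tm = train(build_cnn(cfg), ws, val, cfg)
        _, hard = predict(tm, val)
        assert (hard == val.labels).mean() >= 0.95

    def test_reproducible_from_seed(self):
        ws = separable_windows(60)
        val = separable_windows(20, seed=2)
        cfg = small_cfg(max_epochs=3)
        a = train(build_cnn(cfg), ws, val, cfg)
        b = train(build_cnn(cfg), ws, val, cfg)
        assert a.history == b.history

    def test_early_stopping_patience(self, monkeypatch):
        """A validation loss that plateaus after epoch 1 stops training
        exactly patience epochs later, and the best epoch is recorded."""
        losses = iter([1.0, 0.5, 0.5, 0.5, 0.5, 0.5])
        monkeypatch.setattr(M, "_eval_loss", lambda net, ws: next(losses))
        ws = separable_windows(30)
        val = separable_windows(10, seed=3)
        cfg = small_cfg(max_epochs=10, early_stop_patience=3)
        tm = train(build_cnn(cfg), ws, val, cfg)
        assert tm.best_epoch == 1
        assert len(tm.history) == 5  # epochs 0..4: best at 1, three failures after

    def test_restores_best_weights(self):
        ws = separable_windows(60)
        val = separable_windows(20, seed=2)
        cfg = small_cfg(max_epochs=5)
        tm = train(build_cnn(cfg), ws, val, cfg)
        best = min(h["val_loss"] for h in tm.history)
        assert M._eval_loss(tm.net, val) == pytest.approx(best, abs=1e-7)

    def test_unnormalized_rejected(self):
        ws = separable_windows(10)
        raw = ws.subset(np.arange(ws.n_windows))
        raw.normalized = False
        cfg = small_cfg()
        with pytest.raises(StateError):
            train(build_cnn(cfg), raw, ws, cfg)

    def test_channel_mismatch_rejected(self):
        ws = separable_windows(10, C=6)
        cfg = small_cfg(n_channels=3)
        with pytest.raises(ConfigError):
            train(build_cnn(cfg), ws, ws, cfg)

    def test_empty_training_set(self):
        ws = separable_windows(10)
        empty = ws.subset(np.array([], dtype=int))
        cfg = small_cfg()
        with pytest.raises(DataError):
            train(build_cnn(cfg), empty, ws, cfg)


@pytest.fixture(scope="module")
def trained():
    ws = separable_windows(100)
    val = separable_windows(30, seed=4)
    cfg = small_cfg(max_epochs=5)
    return train(build_cnn(cfg), ws, val, cfg), val


class TestPredict:
    def test_probability_rows(self, trained):
        tm, val = trained
        probs, hard = predict(tm, val)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(hard, probs.argmax(axis=1))

    def test_permutation_equivariance(self, trained):
        tm, val = trained
        perm = np.random.default_rng(0).permutation(val.n_windows)
        p_all, _ = predict(tm, val)
        p_perm, _ = predict(tm, val.subset(perm))
        np.testing.assert_allclose(p_perm, p_all[perm], atol=1e-6)

    def test_acc_only_slice_of_six_channels(self):
        """A 3-channel model consumes the accelerometer slice of
        6-channel windows."""
        ws6 = separable_windows(40, C=6)
        ws3 = ws6.acc_only()
        assert ws3.n_channels == 3
        cfg = small_cfg(max_epochs=2)
        tm = train(build_cnn(cfg), ws3, ws3, cfg)
        probs, _ = predict(tm, ws3)
        assert probs.shape == (ws3.n_windows, 2)

    def test_save_load_roundtrip(self, trained, tmp_path):
        tm, val = trained
        save_model(tm, tmp_path / "model")
        back = load_model(tmp_path / "model")
        p0, _ = predict(tm, val)
        p1, _ = predict(back, val)
        np.testing.assert_array_equal(p0, p1)
        assert back.best_epoch == tm.best_epoch
        assert [h["epoch"] for h in back.history] == [h["epoch"] for h in tm.history]
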