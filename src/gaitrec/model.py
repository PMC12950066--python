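"""A compact 1D convolutional network for window classification.

Architecture (fixed topology, tunable widths)::

    Conv1D(n_filters, kernel_len) + ReLU
    Dropout(rate)
    Conv1D(n_filters, kernel_len) + ReLU
    Dropout(rate)
    MaxPool(pool_len)
    Dropout(rate)
    Flatten
    Dense(dense_units) + ReLU
    Dense(2)
    Softmax

Input batches have shape (batch, window_len, n_channels) with
n_channels 3 (acceleration only) or 6 (acceleration + angular velocity).
The network is implemented directly in numpy: convolutions are lowered to
matrix products via an im2col transform, training uses mini-batch Adam on
the cross-entropy loss, dropout is the inverted variant, and early
stopping monitors validation loss with best-weights restoration.
Everything is seeded, so a fixed (seed, data) pair reproduces training
exactly.

Class order is fixed as (non-walking, walking) = (0, 1) everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, DataError, StateError
from .preprocess import WindowSet

CLASS_ORDER = ("non_walking", "walking")


@dataclass
class ModelConfig:
    """Hyperparameters of the window classifier.

    ``n_channels``, ``window_len``, ``n_filters``, ``dropout_rate``,
    ``batch_size`` and ``early_stop_patience`` are the method's fixed
    design constants; kernel length (9 samples ~ 0.09 s at 100 Hz),
    pooling length, dense width, optimizer and learning rate are
    mainstream defaults exposed here for tuning.
    """

    n_channels: int = 6
    window_len: int = 200
    n_filters: int = 64
    kernel_len: int = 9
    pool_len: int = 2
    dense_units: int = 64
    dropout_rate: float = 0.5
    batch_size: int = 32
    max_epochs: int = 10
    early_stop_patience: int = 3
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels not in (3, 6):
            raise ConfigError("n_channels must be 3 or 6")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.kernel_len >= self.window_len:
            raise ConfigError("kernel_len must be smaller than window_len")
        if self.kernel_len % 2 == 0 or self.kernel_len < 1:
            raise ConfigError("kernel_len must be a positive odd integer")
        if self.pool_len < 1 or self.max_epochs < 1:
            raise ConfigError("pool_len and max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        L2 = self.window_len - 2 * (self.kernel_len - 1)
        if L2 < self.pool_len:
            raise ConfigError("window too short for two convolutions + pooling")


def _he_init(rng, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class CNN1D:
    """Untrained/trainable network holding parameters and layer logic."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        k, f, c = cfg.kernel_len, cfg.n_filters, cfg.n_channels
        self.len_conv1 = cfg.window_len - k + 1
        self.len_conv2 = self.len_conv1 - k + 1
        self.len_pool = self.len_conv2 // cfg.pool_len
        self.flat_dim = self.len_pool * f
        rng = np.random.default_rng(cfg.seed)
        self.params = {
            "W1": _he_init(rng, c * k, (c * k, f)),
            "b1": np.zeros(f, dtype=np.float32),
            "W2": _he_init(rng, f * k, (f * k, f)),
            "b2": np.zeros(f, dtype=np.float32),
            "W3": _he_init(rng, self.flat_dim, (self.flat_dim, cfg.dense_units)),
            "b3": np.zeros(cfg.dense_units, dtype=np.float32),
            "W4": _he_init(rng, cfg.dense_units, (cfg.dense_units, 2)),
            "b4": np.zeros(2, dtype=np.float32),
        }

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- layer primitives -------------------------------------------------

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """(B, T, C) -> (B, T-k+1, C*k) view-reshape for conv-as-matmul."""
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        B, L = cols.shape[0], cols.shape[1]
        return np.ascontiguousarray(cols).reshape(B, L, -1)

    @staticmethod
    def _conv_backward_input(dZ: np.ndarray, W: np.ndarray, k: int, c_in: int) -> np.ndarray:
        """Gradient through the valid conv, accumulated tap by tap
        (avoids materializing a padded im2col of the upstream gradient)."""
        B, L, F = dZ.shape
        Wk = W.reshape(c_in, k, F)
        dX = np.zeros((B, L + k - 1, c_in), dtype=dZ.dtype)
        for j in range(k):
            dX[:, j : j + L] += dZ @ Wk[:, j, :].T
        return dX

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        """Run the network; returns (probabilities, cache-for-backward)."""
        cfg = self.cfg
        p = self.params
        rate = cfg.dropout_rate if train else 0.0

        def dropout(a):
            if rate == 0.0:
                return a, None
            mask = (rng.random(a.shape, dtype=np.float32) >= rate).astype(
                np.float32
            ) / np.float32(1.0 - rate)
            return a * mask, mask

        x = x.astype(np.float32, copy=False)
        c1_cols = self._im2col(x, cfg.kernel_len)
        z1 = c1_cols @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        d1, m1 = dropout(a1)

        c2_cols = self._im2col(d1, cfg.kernel_len)
        z2 = c2_cols @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        d2, m2 = dropout(a2)

        B = x.shape[0]
        pl = cfg.pool_len
        pooled_in = d2[:, : self.len_pool * pl].reshape(B, self.len_pool, pl, -1)
        if pl == 2:
            # first-wins tie rule, matching argmax
            arg = (pooled_in[:, :, 0, :] < pooled_in[:, :, 1, :]).astype(np.int8)
            pool = np.maximum(pooled_in[:, :, 0, :], pooled_in[:, :, 1, :])
        else:
            arg = pooled_in.argmax(axis=2)
            pool = np.take_along_axis(pooled_in, arg[:, :, None, :], axis=2)[:, :, 0, :]
        d3, m3 = dropout(pool)

        flat = d3.reshape(B, -1)
        z4 = flat @ p["W3"] + p["b3"]
        a4 = np.maximum(z4, 0.0)
        z5 = a4 @ p["W4"] + p["b4"]
        z5 = z5 - z5.max(axis=1, keepdims=True)
        ez = np.exp(z5)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache = (x, c1_cols, z1, m1, d1, c2_cols, z2, m2, arg, m3, flat, z4, a4, probs)
        return probs, cache

    def backward(self, cache, y: np.ndarray) -> dict:
        """Cross-entropy gradient for integer labels y (0/1)."""
        cfg = self.cfg
        p = self.params
        (x, c1_cols, z1, m1, d1, c2_cols, z2, m2, arg, m3, flat, z4, a4, probs) = cache
        B = x.shape[0]
        k = cfg.kernel_len

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads = {}
        grads["W4"] = a4.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        da4 = dlogits @ p["W4"].T
        dz4 = da4 * (z4 > 0)
        grads["W3"] = flat.T @ dz4
        grads["b3"] = dz4.sum(axis=0)
        dflat = dz4 @ p["W3"].T

        dpool = dflat.reshape(B, self.len_pool, -1)
        if m3 is not None:
            dpool = dpool * m3
        dd2 = np.zeros((B, self.len_conv2, cfg.n_filters), dtype=np.float32)
        dd2_view = dd2[:, : self.len_pool * cfg.pool_len].reshape(
            B, self.len_pool, cfg.pool_len, -1
        )
        if cfg.pool_len == 2:
            sel = arg.astype(np.float32)
            dd2_view[:, :, 0, :] = dpool * (1.0 - sel)
            dd2_view[:, :, 1, :] = dpool * sel
        else:
            np.put_along_axis(dd2_view, arg[:, :, None, :], dpool[:, :, None, :], axis=2)

        if m2 is not None:
            dd2 = dd2 * m2
        dz2 = dd2 * (z2 > 0)
        grads["W2"] = c2_cols.reshape(-1, c2_cols.shape[-1]).T @ dz2.reshape(
            -1, cfg.n_filters
        )
        grads["b2"] = dz2.sum(axis=(0, 1))
        dd1 = self._conv_backward_input(dz2, p["W2"], k, cfg.n_filters)

        if m1 is not None:
            dd1 = dd1 * m1
        dz1 = dd1 * (z1 > 0)
        grads["W1"] = c1_cols.reshape(-1, c1_cols.shape[-1]).T @ dz1.reshape(
            -1, cfg.n_filters
        )
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads


def build_cnn(cfg: ModelConfig) -> CNN1D:
    """Construct the network with seeded He initialization."""
    return CNN1D(cfg)


@dataclass
class TrainedModel:
    """A trained classifier plus its provenance."""

    net: CNN1D
    config: ModelConfig
    history: list  # per-epoch dicts: epoch, train_loss, val_loss
    best_epoch: int
    class_order: tuple = CLASS_ORDER


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


def _eval_loss(net: CNN1D, ws: WindowSet, chunk: int = 256) -> float:
    losses, ns = [], []
    for i in range(0, ws.n_windows, chunk):
        probs, _ = net.forward(ws.windows[i : i + chunk], train=False)
        losses.append(_cross_entropy(probs, ws.labels[i : i + chunk]))
        ns.append(len(probs))
    return float(np.average(losses, weights=ns))


def train(
    net: CNN1D,
    train_ws: WindowSet,
    val_ws: WindowSet,
    cfg: ModelConfig | None = None,
) -> TrainedModel:
    """Mini-batch Adam on cross-entropy with early stopping.

    Training halts at ``max_epochs`` or once validation loss has failed to
    improve for ``early_stop_patience`` consecutive epochs; the parameters
    from the best-validation-loss epoch are restored.
    """
    cfg = cfg or net.cfg
    for ws, name in ((train_ws, "training"), (val_ws, "validation")):
        if not ws.normalized:
            raise StateError(f"{name} WindowSet must be normalized")
        if ws.n_windows and ws.n_channels != cfg.n_channels:
            raise ConfigError(
                f"{name} windows have {ws.n_channels} channels, "
                f"model expects {cfg.n_channels}"
            )
    if train_ws.n_windows == 0:
        raise DataError("empty training set")

    ss = np.random.SeedSequence(cfg.seed)
    rng_shuffle, rng_drop = (np.random.default_rng(s) for s in ss.spawn(2))
    lr, b1m, b2m, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in net.params.items()}
    t = 0

    history = []
    best_loss, best_params, best_epoch, wait = np.inf, None, -1, 0
    X, y = train_ws.windows, train_ws.labels
    for epoch in range(cfg.max_epochs):
        order = rng_shuffle.permutation(len(y))
        batch_losses = []
        for i in range(0, len(y), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            probs, cache = net.forward(X[idx], train=True, rng=rng_drop)
            batch_losses.append(_cross_entropy(probs, y[idx]))
            grads = net.backward(cache, y[idx])
            t += 1
            # bias-corrected step size folded into the scalar lr_t
            lr_t = lr * np.sqrt(1 - b2m**t) / (1 - b1m**t)
            for key, g in grads.items():
                g = g.astype(np.float32, copy=False)
                mk, vk = m[key], v[key]
                mk *= b1m
                mk += (1 - b1m) * g
                vk *= b2m
                vk += (1 - b2m) * np.square(g)
                net.params[key] -= lr_t * mk / (np.sqrt(vk) + eps)
        val_loss = _eval_loss(net, val_ws) if val_ws.n_windows else float("nan")
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss:
            best_loss, best_epoch, wait = val_loss, epoch, 0
            best_params = {k: p.copy() for k, p in net.params.items()}
        else:
            wait += 1
            if wait >= cfg.early_stop_patience:
                break
    if best_params is not None:
        net.params = best_params
    return TrainedModel(net=net, config=cfg, history=history, best_epoch=best_epoch)


def predict(tm: TrainedModel, ws: WindowSet, chunk: int = 256):
    """Per-window class probabilities and hard labels (argmax).

    Probability columns follow ``tm.class_order`` = (non-walking, walking).
    """
    if not ws.normalized:
        raise StateError("windows must be normalized before prediction")
    if ws.n_windows and ws.n_channels != tm.config.n_channels:
        raise ConfigError(
            f"windows have {ws.n_channels} channels, model expects "
            f"{tm.config.n_channels}"
        )
    probs = np.empty((ws.n_windows, 2), dtype=np.float32)
    for i in range(0, ws.n_windows, chunk):
        probs[i : i + chunk], _ = tm.net.forward(ws.windows[i : i + chunk], train=False)
    return probs, probs.argmax(axis=1).astype(np.int8)


def save_model(tm: TrainedModel, out_dir) -> None:
    """Model artifact: config + history as text, parameters as .npz."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(
            {
                "model_config": asdict(tm.config),
                "best_epoch": tm.best_epoch,
                "class_order": list(tm.class_order),
            },
            indent=2,
        )
    )
    np.savez(out / "params.npz", **tm.net.params)
    with open(out / "history.csv", "w", encoding="utf-8") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for h in tm.history:
            fh.write(f"{h['epoch']},{h['train_loss']},{h['val_loss']}\n")


def load_model(model_dir) -> TrainedModel:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "config.json").read_text())
    cfg = ModelConfig(**meta["model_config"])
    net = CNN1D(cfg)
    with np.load(model_dir / "params.npz") as npz:
        net.params = {k: npz[k] for k in npz.files}
    history = []
    for line in (model_dir / "history.csv").read_text().splitlines()[1:]:
        e, tr, va = line.split(",")
        history.append(
            {"epoch": int(e), "train_loss": float(tr), "val_loss": float(va)}
        )
    return TrainedModel(
        net=net,
        config=cfg,
        history=history,
        best_epoch=meta["best_epoch"],
        class_order=tuple(meta["class_order"]),
    )
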