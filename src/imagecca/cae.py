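"""Convolutional autoencoder for histology windows, plus a supervised head.

The encoder stacks ``n_conv_layers`` blocks of 5x5 same-padding convolution,
ReLU and 2x2 max pooling, doubling the filter count at each block, and ends
in a fully connected bottleneck (default 1024 units).  The decoder mirrors
it: a linear projection reshaped to the last encoder feature map, then
blocks of nearest-neighbour 2x upsampling, 5x5 convolution and ReLU, with a
final sigmoid onto [0, 1] pixel intensities.  Training minimises the mean
squared reconstruction error on randomly sampled 128x128 image windows.

A small multi-layer perceptron head (128 ReLU units, then softmax — or a
single sigmoid unit for two classes) can be attached to the trained encoder
for cancer / tissue classification; its 128-unit hidden activations serve
as supervised image features.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import (
    Adam,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2,
    ReLU,
    Reshape,
    Sequential,
    Sigmoid,
    UpSample2,
)

__all__ = [
    "CAEConfig",
    "MLPHeadConfig",
    "CAE",
    "MLPHead",
    "build_cae",
    "train_cae",
    "encode",
    "train_mlp_head",
    "classify_patches",
]


@dataclass
class CAEConfig:
    """Architecture and training settings for the autoencoder."""

    n_conv_layers: int = 4
    base_filters: int = 32
    kernel: int = 5
    pool: int = 2
    code_dim: int = 1024
    input_size: int = 128
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.code_dim < 1:
            raise ValueError("code_dim must be >= 1")
        if self.input_size % (self.pool ** self.n_conv_layers) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"pool^n_conv_layers = {self.pool ** self.n_conv_layers}"
            )

    @property
    def encoder_filters(self) -> list[int]:
        return [self.base_filters * 2 ** i for i in range(self.n_conv_layers)]

    @property
    def encoder_map_sizes(self) -> list[int]:
        return [self.input_size // self.pool ** (i + 1) for i in range(self.n_conv_layers)]


@dataclass
class MLPHeadConfig:
    """Classifier head settings; binary problems may use one sigmoid unit."""

    hidden_units: int = 128
    n_classes: int = 2
    binary_sigmoid: bool = False
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.binary_sigmoid and self.n_classes != 2:
            raise ValueError("sigmoid output only valid for 2 classes")


class CAE:
    """Autoencoder with separately addressable encoder and decoder stacks."""

    def __init__(self, config: CAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        s = c.input_size // c.pool ** c.n_conv_layers  # final map size
        f_last = c.encoder_filters[-1]

        enc: list = []
        c_in = 3
        for f in c.encoder_filters:
            enc += [Conv2D(c_in, f, c.kernel, rng), ReLU(), MaxPool2()]
            c_in = f
        enc += [Flatten(), Dense(s * s * f_last, c.code_dim, rng)]
        self.encoder = Sequential(enc)

        dec: list = [Dense(c.code_dim, s * s * f_last, rng), Reshape((s, s, f_last))]
        filters = list(reversed(c.encoder_filters[:-1])) + [3]
        c_in = f_last
        for i, f in enumerate(filters):
            dec += [UpSample2(), Conv2D(c_in, f, c.kernel, rng)]
            dec.append(Sigmoid() if i == len(filters) - 1 else ReLU())
            c_in = f
        self.decoder = Sequential(dec)

    # -- forward/backward -------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        """Map (N, H, W, 3) windows in [0,1] to (N, code_dim) codes."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return self.encoder.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(dout))

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    @property
    def grads(self):
        return self.encoder.grads + self.decoder.grads

    def describe(self) -> dict:
        c = self.config
        return {
            "encoder_filters": c.encoder_filters,
            "encoder_map_sizes": c.encoder_map_sizes,
            "code_dim": c.code_dim,
            "input_size": c.input_size,
        }

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path, _format_version=np.int64(1), **arrays)

    @classmethod
    def load(cls, path, config: CAEConfig) -> "CAE":
        model = cls(config)
        with np.load(path) as z:
            for i, p in enumerate(model.params):
                p[...] = z[f"p{i}"]
        return model


def build_cae(config: CAEConfig) -> CAE:
    """Construct an untrained autoencoder (weights seeded from config)."""
    return CAE(config)


def _as_window_array(windows) -> np.ndarray:
    """Accept a WindowBatch-like object or a plain (m, H, W, 3) array."""
    arr = getattr(windows, "windows", windows)
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected (m, H, W, 3) window stack, got {arr.shape}")
    return arr


def train_cae(windows, config: CAEConfig, model: CAE | None = None):
    """Train the autoencoder on a stack of windows.

    Returns ``(model, loss_history)`` where ``loss_history[e]`` is the mean
    per-batch MSE of epoch ``e``.  Raises on non-finite loss.
    """
    x = _as_window_array(windows)
    model = model or build_cae(config)
    opt = Adam(model.params, model.grads, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            batch = x[order[start:start + config.batch_size]]
            recon = model.forward(batch)
            loss, dout = _nn.mse_loss_grad(recon, batch)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite reconstruction loss at epoch {epoch}, "
                    f"batch starting {start} (lr={config.learning_rate})"
                )
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def encode(windows, model: CAE, batch_size: int = 64) -> np.ndarray:
    """Encode windows to an (m, code_dim) matrix with the trained encoder."""
    x = _as_window_array(windows)
    if x.shape[1] != model.config.input_size or x.shape[2] != model.config.input_size:
        raise ValueError(
            f"window size {x.shape[1:3]} incompatible with encoder input "
            f"{model.config.input_size}"
        )
    out = [model.encode(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    codes = np.concatenate(out, axis=0)
    if not np.all(np.isfinite(codes)):
        raise RuntimeError("non-finite values in encoded windows")
    return codes


class MLPHead:
    """Dense(code -> hidden ReLU) -> Dense(hidden -> classes) classifier."""

    def __init__(self, code_dim: int, config: MLPHeadConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        n_out = 1 if config.binary_sigmoid else config.n_classes
        self.hidden = Dense(code_dim, config.hidden_units, rng)
        self.relu = ReLU()
        self.out = Dense(config.hidden_units, n_out, rng)
        self.net = Sequential([self.hidden, self.relu, self.out])

    def logits(self, codes: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(codes, dtype=np.float32))

    def hidden_activations(self, codes: np.ndarray) -> np.ndarray:
        """128-unit hidden-layer activations (the supervised features)."""
        h = self.hidden.forward(np.asarray(codes, dtype=np.float32))
        return np.maximum(h, 0)

    def predict_proba(self, codes: np.ndarray) -> np.ndarray:
        z = self.logits(codes)
        if self.config.binary_sigmoid:
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        return _nn.softmax(z)

    def predict(self, codes: np.ndarray) -> np.ndarray:
        return self.predict_proba(codes).argmax(axis=1)

    def fit(self, codes: np.ndarray, labels: np.ndarray,
            encoder: CAE | None = None, windows=None):
        """Train by cross-entropy; if ``encoder`` and ``windows`` are given,
        gradients flow into the encoder (fine-tuning), else codes are fixed."""
        cfg = self.config
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("training labels contain a single class")
        fine_tune = encoder is not None
        params = self.net.params + (encoder.params if fine_tune else [])
        grads = self.net.grads + (encoder.grads if fine_tune else [])
        opt = Adam(params, grads, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)
        n = len(labels)
        history = []
        x = _as_window_array(windows) if fine_tune else np.asarray(codes, np.float32)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                if fine_tune:
                    c = encoder.encoder.forward(x[idx])
                else:
                    c = x[idx]
                z = self.net.forward(c)
                if cfg.binary_sigmoid:
                    loss, dz = _nn.sigmoid_xent_grad(z, labels[idx])
                else:
                    loss, dz = _nn.softmax_xent_grad(z, labels[idx], cfg.n_classes)
                dc = self.net.backward(dz)
                if fine_tune:
                    encoder.encoder.backward(dc)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history


def train_mlp_head(model: CAE, windows, labels: Sequence[int],
                   config: MLPHeadConfig, fine_tune: bool = False):
    """Train the classifier head on encoder codes of labelled windows.

    Returns ``(head, loss_history)``.  With ``fine_tune=True`` the encoder
    weights are updated jointly with the head; otherwise they are frozen.
    """
    labels = np.asarray(labels)
    if fine_tune:
        head = MLPHead(model.config.code_dim, config)
        history = head.fit(None, labels, encoder=model, windows=windows)
    else:
        codes = encode(windows, model)
        head = MLPHead(codes.shape[1], config)
        history = head.fit(codes, labels)
    return head, history


def classify_patches(image: np.ndarray, model: CAE, head: MLPHead,
                     stride: int = 8, batch_size: int = 64) -> np.ndarray:
    """Dense patch classification heatmap.

    Slides the encoder's input window over ``image`` with the given stride
    and reports the class-1 probability of each patch; output shape is
    (floor((H-w)/stride)+1, floor((W-w)/stride)+1).
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    else:
        img = img.astype(np.float32)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    w = model.config.input_size
    H, W = img.shape[:2]
    if H < w or W < w:
        raise ValueError(f"image {H}x{W} smaller than patch size {w}")
    rows = (H - w) // stride + 1
    cols = (W - w) // stride + 1
    heat = np.empty((rows, cols), dtype=np.float32)
    patches, coords = [], []

    def _flush():
        if not patches:
            return
        codes = model.encode(np.stack(patches))
        probs = head.predict_proba(codes)[:, 1]
        for (r, c), p in zip(coords, probs):
            heat[r, c] = p
        patches.clear()
        coords.clear()

    for r in range(rows):
        for c in range(cols):
            patches.append(img[r * stride:r * stride + w, c * stride:c * stride + w, :])
            coords.append((r, c))
            if len(patches) >= batch_size:
                _flush()
    _flush()
    return heat
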