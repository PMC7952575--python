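"""Minimal feed-forward neural-network layers on numpy.

Implements exactly the pieces the autoencoder and classifier head need:
same-padding 2-D convolution (im2col), 2x2 max pooling, nearest-neighbour
2x upsampling, dense layers, ReLU/sigmoid nonlinearities and an Adam
optimizer.  All arrays are float32, NHWC layout.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv2D",
    "MaxPool2",
    "UpSample2",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "softmax",
    "mse_loss_grad",
    "softmax_xent_grad",
    "sigmoid_xent_grad",
]


class Layer:
    """Base layer: stateless unless it has ``params``/``grads`` lists."""

    params: list = []
    grads: list = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Conv2D(Layer):
    """Same-padding, stride-1 convolution.

    Input (N, H, W, C_in) -> output (N, H, W, C_out); odd kernel only.
    Both passes accumulate over the k*k kernel offsets with broadcast
    matmuls on shifted slices of the padded input, which keeps peak memory
    at one feature map and streams well on a single core.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        fan_in = kernel * kernel * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((kernel, kernel, c_in, c_out)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self.c_in = c_in
        self.c_out = c_out

    def forward(self, x):
        k, pad = self.k, self.k // 2
        n, h, w, _ = x.shape
        self._shape = (n, h, w)
        xp = np.pad(x.astype(np.float32, copy=False),
                    ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        self._xp = xp
        out = np.empty((n, h, w, self.c_out), dtype=np.float32)
        out[:] = self.b
        for ki in range(k):
            for kj in range(k):
                out += xp[:, ki:ki + h, kj:kj + w, :] @ self.W[ki, kj]
        return out

    def backward(self, dout):
        n, h, w = self._shape
        k, pad = self.k, self.k // 2
        xp = self._xp
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        self.db[...] = dout.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, ki:ki + h, kj:kj + w, :]
                self.dW[ki, kj] = np.tensordot(xs, dout, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, ki:ki + h, kj:kj + w, :] += dout @ self.W[ki, kj].T
        self._xp = None  # free the cached padded input
        return dxp[:, pad:pad + h, pad:pad + w, :]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self._shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2)
        dx = dx.transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        return dx


class UpSample2(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape  # per-sample shape

    def forward(self, x):
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dout):
        return dout.reshape(dout.shape[0], -1)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def mse_loss_grad(pred, target):
    """Mean squared error over all elements; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 / diff.size) * diff.astype(np.float32)


def softmax_xent_grad(logits, labels, n_classes):
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


def sigmoid_xent_grad(logit, labels):
    """Binary cross-entropy on a single logit column; labels in {0,1}."""
    p = 1.0 / (1.0 + np.exp(-logit[:, 0]))
    n = logit.shape[0]
    loss = float(-np.mean(labels * np.log(p + 1e-12) + (1 - labels) * np.log(1 - p + 1e-12)))
    dlogit = ((p - labels) / n).astype(np.float32)[:, None]
    return loss, dlogit
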