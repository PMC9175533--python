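"""Minimal feed-forward/convolutional network engine (numpy, manual backprop).

Provides exactly what the transfer-learning harness needs: 2-D
convolution (same padding, im2col), ReLU, 2x2 max pooling, flatten,
dense layers, inverted dropout, a binary-cross-entropy-with-logits
loss, and an Adam optimizer that honours per-layer ``trainable`` flags
so backbone blocks can be frozen and later unfrozen.  All randomness
(initialization, dropout masks) flows through explicit
``numpy.random.Generator`` objects.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    z = logits.ravel()
    y = targets.ravel().astype(float)
    # log(1 + e^z) computed stably
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(softplus - y * z))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(logits.shape)


class Layer:
    """Base layer: forward/backward plus (param, grad) exposure."""

    trainable = True

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_and_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    @property
    def has_params(self) -> bool:
        return bool(self.params_and_grads())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He init, ReLU-friendly
        self.w = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches with same (zero) padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.standard_normal((c_out, c_in, k, k)) * scale
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._xshape = x.shape
        self._cols = _im2col(x, self.k)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = self._cols @ wmat.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w = self._xshape
        f = self.w.shape[0]
        g = grad.transpose(0, 2, 3, 1).reshape(-1, f)
        wmat = self.w.reshape(f, -1)
        self.dw = (g.T @ self._cols).reshape(self.w.shape)
        self.db = g.sum(axis=0)
        dcols = g @ wmat  # (N*H*W, C*k*k)
        return _col2im(dcols, self._xshape, self.k)

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


def _col2im(cols: np.ndarray, xshape: tuple, k: int) -> np.ndarray:
    """Scatter-add of im2col patches back onto the padded input grid."""
    n, c, h, w = xshape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
    cols = cols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, p : p + h, p : p + w]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input H, W must be even)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._arg = np.argmax(r, axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._xshape
        out = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Sequential:
    """Ordered layer stack with frozen-prefix-aware backward."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        # stop propagating once every remaining (earlier) layer is frozen
        first_trainable = 0
        for i, layer in enumerate(self.layers):
            if layer.has_params and layer.trainable:
                first_trainable = i
                break
        else:
            return
        for layer in reversed(self.layers[first_trainable:]):
            grad = layer.backward(grad)

    def trainable_params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            if layer.trainable:
                out.extend(layer.params_and_grads())
        return out

    def checksum(self, only_frozen: bool = False) -> float:
        """Deterministic digest of parameter values (freeze verification)."""
        total = 0.0
        for layer in self.layers:
            if only_frozen and layer.trainable:
                continue
            for p, _ in layer.params_and_grads():
                total += float(np.sum(np.abs(p))) + float(np.sum(p * p))
        return total


class Adam:
    """Adam optimizer over a Sequential's currently trainable parameters.

    State is keyed by parameter identity, so freezing/unfreezing layers
    mid-training (the two-stage transfer schedule) just changes which
    parameters receive updates.
    """

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._state: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}

    def step(self, model: Sequential) -> None:
        for p, g in model.trainable_params():
            key = id(p)
            m, v, t = self._state.get(key, (np.zeros_like(p), np.zeros_like(p), 0))
            t += 1
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**t)
            vhat = v / (1 - self.beta2**t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            self._state[key] = (m, v, t)
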