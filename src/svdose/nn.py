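"""Minimal CPU neural-network kernels for volumetric binary classification.

Implements exactly the pieces the dose classifier needs — 3D convolution
('same' padding, stride 1) via im2col + BLAS GEMM, 2x2x2 max pooling, ReLU,
dense layers, a sigmoid head with a numerically stable binary cross-entropy
on logits, and the Adam optimiser — in float32 NumPy.  Everything is
deterministic given a seed on a fixed device/BLAS.

Layout convention: activations are channels-last,
``(n, length, width, depth, channels)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray) -> np.ndarray:
    """(n, L, W, D, C) -> (n*L*W*D, 27*C) patches of the 3x3x3 neighbourhood."""
    n, l, w, d, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
    # window axes before channel axis so weight rows are (offset, channel)
    col = win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(n * l * w * d, 27 * c)
    return np.ascontiguousarray(col, dtype=np.float32)


def _col2im(dcol: np.ndarray, x_shape) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to the input grid."""
    n, l, w, d, c = x_shape
    dxp = np.zeros((n, l + 2, w + 2, d + 2, c), dtype=np.float32)
    dcol = dcol.reshape(n, l, w, d, 3, 3, 3, c)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                dxp[:, i:i + l, j:j + w, k:k + d, :] += dcol[:, :, :, :, i, j, k, :]
    return dxp[:, 1:-1, 1:-1, 1:-1, :]


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 first: bool = False):
        super().__init__()
        fan_in = 27 * c_in
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 (fan_in, c_out)).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self.first = first  # input gradient not needed for the first layer
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x, train=False):
        self._x_shape = x.shape
        col = _im2col(x)
        self._col = col if train else None
        y = col @ self.weight
        y += self.bias
        n, l, w, d, _ = x.shape
        return y.reshape(n, l, w, d, self.c_out)

    def backward(self, dy):
        n, l, w, d, _ = self._x_shape
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(-1, self.c_out)
        self.grads[0][...] = self._col.T @ dyf
        self.grads[1][...] = dyf.sum(axis=0)
        self._col = None
        if self.first:
            return None
        dcol = dyf @ self.weight.T
        return _col2im(dcol, self._x_shape)

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2 (spatial extents must be even)."""

    def forward(self, x, train=False):
        n, l, w, d, c = x.shape
        if l % 2 or w % 2 or d % 2:
            raise ValueError(f"pooling needs even spatial extents, got {x.shape}")
        xr = x.reshape(n, l // 2, 2, w // 2, 2, d // 2, 2, c)
        xt = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 7, 2, 4, 6))
        xt = xt.reshape(n, l // 2, w // 2, d // 2, c, 8)
        idx = xt.argmax(axis=-1)
        out = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape = idx, x.shape
        return out

    def backward(self, dy):
        n, l, w, d, c = self._in_shape
        dxt = np.zeros((n, l // 2, w // 2, d // 2, c, 8), dtype=np.float32)
        np.put_along_axis(dxt, self._idx[..., None],
                          dy[..., None].astype(np.float32), axis=-1)
        dxt = dxt.reshape(n, l // 2, w // 2, d // 2, c, 2, 2, 2)
        dx = dxt.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(n, l, w, d, c)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu_fan: bool = True):
        super().__init__()
        scale = np.sqrt((2.0 if relu_fan else 1.0) / n_in)
        self.weight = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.bias = np.zeros(n_out, dtype=np.float32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.weight + self.bias

    def backward(self, dy):
        dy = dy.astype(np.float32, copy=False)
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.weight.T

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of logits ``z`` against labels ``y``."""
    z = np.asarray(z, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    # softplus(z) - y*z, with softplus computed stably
    loss = np.logaddexp(0.0, z) - y * z
    return float(loss.mean())


def bce_from_probs(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(np.asarray(p, dtype=np.float64).ravel(), eps, 1 - eps)
    y = np.asarray(y, dtype=np.float64).ravel()
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class Adam:
    """Adam optimiser (Kingma & Ba) over a list of layers' parameters."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.slots = []
        for layer in layers:
            for p in layer.params:
                self.slots.append(
                    (p, np.zeros_like(p, dtype=np.float32),
                     np.zeros_like(p, dtype=np.float32))
                )
        self._layers = layers
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        i = 0
        for layer in self._layers:
            for p, g in zip(layer.params, layer.grads):
                _, m, v = self.slots[i]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * np.square(g)
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                i += 1


class Sequential:
    """An ordered layer stack with logit output."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out  # logits, shape (n, 1)

    def backward(self, dlogits) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break

    def predict_proba(self, x, batch_size: int = 32) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            z = self.forward(x[i:i + batch_size], train=False)
            probs.append(sigmoid(z).ravel())
        return np.concatenate(probs)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)
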