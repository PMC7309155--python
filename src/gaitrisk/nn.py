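"""Minimal NumPy building blocks for small convolutional classifiers.

Implements just what the frame classifier needs — valid-mode Conv2D,
max-pooling, dense layers, ReLU/sigmoid, class-weighted binary
cross-entropy and Adam — with exact analytic gradients and fully
seed-deterministic behaviour (single-threaded NumPy primitives only).
Convolutions are lowered to im2col matrix products so the heavy lifting is
one BLAS GEMM per layer. Arrays are float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Sequential",
    "Adam",
    "bce_loss",
]


class Layer:
    params: tuple = ()

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv2D(Layer):
    """Valid cross-correlation, kernels (out, in, kh, kw), He-initialized."""

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int, rng: np.random.Generator, stride_w: int = 1):
        scale = np.sqrt(2.0 / (c_in * kh * kw))
        self.w = (rng.standard_normal((c_out, c_in, kh, kw)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.stride_w = stride_w
        self.params = ("w", "b")

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        kh, kw = self.w.shape[2], self.w.shape[3]
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        if self.stride_w > 1:
            win = win[:, :, :, :: self.stride_w]
        b, c, ho, wo = win.shape[:4]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, c * kh * kw
        )
        return cols, (b, ho, wo)

    def forward(self, x, train=False):
        cols, (b, ho, wo) = self._im2col(x)
        if train:
            self._cols, self._x_shape, self._out_hw = cols, x.shape, (ho, wo)
        c_out = self.w.shape[0]
        wmat = self.w.reshape(c_out, -1)
        out = cols @ wmat.T + self.b
        return out.reshape(b, ho, wo, c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        c_out, c_in, kh, kw = self.w.shape
        b, _, ho, wo = grad.shape
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        self.dw = (gmat.T @ self._cols).reshape(self.w.shape).astype(np.float32)
        self.db = gmat.sum(axis=0).astype(np.float32)
        dcols = gmat @ self.w.reshape(c_out, -1)  # (B*ho*wo, C*kh*kw)
        dcols = dcols.reshape(b, ho, wo, c_in, kh, kw)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        sw = self.stride_w
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + ho, j : j + (wo - 1) * sw + 1 : sw] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping (ph, pw) max pooling; trailing remainder is cropped."""

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        h2, w2 = h // self.ph, w // self.pw
        xr = x[:, :, : h2 * self.ph, : w2 * self.pw]
        xr = xr.reshape(b, c, h2, self.ph, w2, self.pw).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(b, c, h2, w2, self.ph * self.pw)
        idx = flat.argmax(axis=-1)
        if train:
            self._idx, self._in_shape = idx, x.shape
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        b, c, h, w = self._in_shape
        h2, w2 = grad.shape[2], grad.shape[3]
        flat = np.zeros((b, c, h2, w2, self.ph * self.pw), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        out = np.zeros(self._in_shape, dtype=np.float32)
        out[:, :, : h2 * self.ph, : w2 * self.pw] = (
            flat.reshape(b, c, h2, w2, self.ph, self.pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h2 * self.ph, w2 * self.pw)
        )
        return out


class GlobalAvgPool(Layer):
    """Mean over the spatial axes: (B, C, H, W) -> (B, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(
            (grad / (h * w))[:, :, None, None], self._shape
        ).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = ("w", "b")

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = (self._x.T @ grad).astype(np.float32)
        self.db = grad.sum(axis=0).astype(np.float32)
        return (grad @ self.w.T).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, np.float32(0.0), out=x)

    def backward(self, grad):
        grad[~self._mask] = 0.0
        return grad


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        return self._y.astype(np.float32)

    def backward(self, grad):
        return (grad * self._y * (1.0 - self._y)).astype(np.float32)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def state(self) -> list:
        return [getattr(layer, name).copy() for layer, name in self.parameters()]

    def load_state(self, state: list) -> None:
        for (layer, name), value in zip(self.parameters(), state):
            setattr(layer, name, value.copy())


def bce_loss(
    p: np.ndarray, y: np.ndarray, pos_weight: float = 1.0, eps: float = 1e-7
) -> tuple[float, np.ndarray]:
    """(Weighted) binary cross-entropy and its gradient w.r.t. the output.

    ``pos_weight`` multiplies the positive-class term; setting it to
    n_negative/n_positive rebalances an imbalanced training set.
    """
    p = np.clip(p.astype(np.float64), eps, 1.0 - eps)
    y = y.astype(np.float64)
    w = np.where(y == 1, pos_weight, 1.0)
    norm = w.sum()
    loss = float(np.sum(w * (-y * np.log(p) - (1.0 - y) * np.log(1.0 - p))) / norm)
    grad = (w * (p - y) / (p * (1.0 - p)) / norm).astype(np.float32)
    return loss, grad


class Adam:
    """Adam with optional decoupled weight decay (AdamW when > 0)."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n in model.parameters()]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in model.parameters()]

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.model.parameters()):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(layer, name)
            if self.wd > 0.0 and name == "w":
                p = p * (1.0 - self.lr * self.wd)
            setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
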