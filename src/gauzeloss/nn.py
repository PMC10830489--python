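"""Minimal neural-network core used by the tile classifier and the EBL regressors.

Lightweight, CPU-oriented layers on NHWC numpy arrays with hand-written
backward passes and an Adam optimizer.  Everything is deterministic given the
``numpy.random.Generator`` used at construction time: initialization,
mini-batch order and the arithmetic itself involve no hidden global state.

Layers store their inputs during ``forward(..., train=True)`` so ``backward``
can be called immediately afterwards; inference calls with ``train=False``
keep no state.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_DTYPE = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: parameters and gradients are parallel lists of arrays."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return list(zip(self.params, self.grads))

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        self.w = _he_init(rng, (n_in, n_out), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, (k * k * c_in, c_out), k * k * c_in, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
        n, h, w = x.shape[:3]
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * self.c_in)

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        out = (cols @ self.w + self.b).reshape(n, h, w, self.c_out)
        if train:
            self._cols, self._shape = cols, x.shape
        return out

    def backward(self, grad):
        n, h, w, c_in = self._shape
        k = self.k
        p = k // 2
        g2 = grad.reshape(n * h * w, self.c_out)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dcols = (g2 @ self.w.T).reshape(n, h, w, k, k, c_in)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c_in), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class DepthwiseConv2D(Layer):
    """Per-channel kxk convolution (same padding, stride 1)."""

    def __init__(self, c: int, rng: np.random.Generator, k: int = 3,
                 dtype=DEFAULT_DTYPE) -> None:
        super().__init__()
        self.k, self.c = k, c
        self.w = _he_init(rng, (k, k, c), k * k, dtype)
        self.b = np.zeros(c, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._win: np.ndarray | None = None

    def forward(self, x, train=False):
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
        out = np.einsum('nhwcij,ijc->nhwc', win, self.w,
                        optimize=True) + self.b
        if train:
            self._win, self._shape = win, x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        k = self.k
        p = k // 2
        self.grads[0][...] = np.einsum('nhwcij,nhwc->ijc', self._win, grad,
                                       optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += grad * self.w[i, j]
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class Swish(Layer):
    """x * sigmoid(x)."""

    def forward(self, x, train=False):
        s = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._x, self._s = x, s
        return x * s

    def backward(self, grad):
        s = self._s
        return grad * (s + self._x * s * (1 - s))


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dxr).reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               (n, h, w, c)).astype(grad.dtype)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    def backward(self, grad):
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad

    def parameters(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.parameters())
        return out

    @property
    def n_params(self):
        return sum(lyr.n_params for lyr in self.layers)


class Parallel(Layer):
    """Run branches on the same input; concatenate outputs on the channel axis."""

    def __init__(self, branches: Sequence[Layer]) -> None:
        super().__init__()
        self.branches = list(branches)

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(grad, splits, axis=-1)
        dx = None
        for b, g in zip(self.branches, parts):
            d = b.backward(np.ascontiguousarray(g))
            dx = d if dx is None else dx + d
        return dx

    def parameters(self):
        out = []
        for b in self.branches:
            out.extend(b.parameters())
        return out

    @property
    def n_params(self):
        return sum(b.n_params for b in self.branches)


class Residual(Layer):
    """x + body(x); body must preserve the channel count."""

    def __init__(self, body: Layer) -> None:
        super().__init__()
        self.body = body

    def forward(self, x, train=False):
        return x + self.body.forward(x, train=train)

    def backward(self, grad):
        return grad + self.body.backward(grad)

    def parameters(self):
        return self.body.parameters()

    @property
    def n_params(self):
        return self.body.n_params


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

KNOWN_BACKBONES = ("small_cnn", "vgg16_style", "googlenet_style",
                   "efficientnet_b3_style", "efficientnet_b5_style")


def _mbconv(c_in: int, c_out: int, rng, dtype, expand: int = 3) -> Layer:
    body = Sequential([
        Conv2D(c_in, c_in * expand, rng, k=1, dtype=dtype), Swish(),
        DepthwiseConv2D(c_in * expand, rng, k=3, dtype=dtype), Swish(),
        Conv2D(c_in * expand, c_out, rng, k=1, dtype=dtype),
    ])
    if c_in == c_out:
        return Residual(body)
    return body


def make_backbone(name: str, c_in: int, rng: np.random.Generator,
                  dtype=DEFAULT_DTYPE) -> tuple[Sequential, int]:
    """Build a feature-extraction backbone ending in global average pooling.

    Returns (backbone, feature_dim).  All variants are small CPU-scale
    reconstructions of the cited design families, not pretrained networks.
    """
    if name == "small_cnn":
        widths = (8, 16, 24)
        layers: list[Layer] = []
        prev = c_in
        for w in widths:
            layers += [Conv2D(prev, w, rng, dtype=dtype), ReLU(), MaxPool2()]
            prev = w
        layers.append(GlobalAvgPool())
        return Sequential(layers), widths[-1]
    if name == "vgg16_style":
        widths = (8, 16, 32)
        layers = []
        prev = c_in
        for w in widths:  # VGG pattern: paired 3x3 convs per stage
            layers += [Conv2D(prev, w, rng, dtype=dtype), ReLU(),
                       Conv2D(w, w, rng, dtype=dtype), ReLU(), MaxPool2()]
            prev = w
        layers.append(GlobalAvgPool())
        return Sequential(layers), widths[-1]
    if name == "googlenet_style":
        def inception(cin, c1, c3, c5):
            return Parallel([
                Sequential([Conv2D(cin, c1, rng, k=1, dtype=dtype), ReLU()]),
                Sequential([Conv2D(cin, c3, rng, k=3, dtype=dtype), ReLU()]),
                Sequential([Conv2D(cin, c5, rng, k=5, dtype=dtype), ReLU()]),
            ])
        layers = [Conv2D(c_in, 8, rng, dtype=dtype), ReLU(), MaxPool2(),
                  inception(8, 4, 8, 4), MaxPool2(),
                  inception(16, 8, 16, 8), MaxPool2(),
                  GlobalAvgPool()]
        return Sequential(layers), 32
    if name in ("efficientnet_b3_style", "efficientnet_b5_style"):
        deep = name.endswith("b5_style")
        widths = (12, 20, 32) if deep else (8, 16, 24)
        layers = [Conv2D(c_in, widths[0], rng, dtype=dtype), Swish(),
                  MaxPool2()]
        prev = widths[0]
        for w in widths[1:]:
            layers += [_mbconv(prev, w, rng, dtype), MaxPool2()]
            prev = w
        if deep:
            layers.insert(-1, _mbconv(prev, prev, rng, dtype))
        layers.append(GlobalAvgPool())
        return Sequential(layers), widths[-1]
    raise ValueError(f"unknown backbone {name!r}; known: {KNOWN_BACKBONES}")


def make_mlp(n_in: int, hidden: Sequence[int], rng: np.random.Generator,
             dtype=DEFAULT_DTYPE) -> tuple[Sequential, int]:
    """Fully connected stack with ReLU between layers; returns (mlp, out_dim)."""
    layers: list[Layer] = []
    prev = n_in
    for h in hidden:
        layers += [Dense(prev, h, rng, dtype=dtype), ReLU()]
        prev = h
    return Sequential(layers), prev


# ---------------------------------------------------------------------------
# optimizer and losses
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray,
                       labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    g = p
    g[np.arange(n), labels] -= 1.0
    return loss, (g / n).astype(logits.dtype)


def regression_loss_grad(pred: np.ndarray, target: np.ndarray,
                         loss: str) -> tuple[float, np.ndarray]:
    """MAE or MSE over a batch and the gradient w.r.t. predictions."""
    d = pred.astype(np.float64) - target.astype(np.float64)
    n = d.size
    if loss == "mae":
        return float(np.abs(d).mean()), (np.sign(d) / n).astype(pred.dtype)
    if loss == "mse":
        return float((d * d).mean()), (2.0 * d / n).astype(pred.dtype)
    raise ValueError(f"unknown loss {loss!r}")


def get_state(layer: Layer) -> list[np.ndarray]:
    return [p.copy() for p, _ in layer.parameters()]


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    for (p, _), s in zip(layer.parameters(), state):
        p[...] = s
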