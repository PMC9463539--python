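"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the pieces the radiograph classifiers need: 2-D
convolution (im2col + BLAS matmul), batch normalization, ReLU/tanh/sigmoid,
max/average pooling, global average pooling, linear layers, an embedding
table, inverted dropout, residual blocks, and SGD with momentum and
per-parameter-group learning rates / weight decays.

Conventions: activations are ``float32`` arrays shaped ``(B, C, H, W)`` for
spatial layers and ``(B, D)`` for dense layers.  Each layer caches what its
backward pass needs during ``forward(..., train=True)``; ``backward`` both
returns the input gradient and accumulates parameter gradients in ``.grads``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Identity",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Linear",
    "Embedding",
    "Dropout",
    "Sequential",
    "ResidualBlock",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


class Layer:
    """Base class: parameters live in ``.params``, gradients in ``.grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.params["W"] = _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=np.float32)
            self.grads["b"] = np.zeros_like(self.params["b"])

    def _cols(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        B, C, H, W = x.shape
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, Ho * Wo, C * k * k
        )
        return cols, Ho, Wo

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.dtype != np.float32 or not x.flags["C_CONTIGUOUS"]:
            x = np.ascontiguousarray(x, dtype=np.float32)
        cols, Ho, Wo = self._cols(x)
        Wmat = self.params["W"].reshape(self.out_ch, -1)
        out = cols.reshape(-1, cols.shape[-1]) @ Wmat.T
        if "b" in self.params:
            out += self.params["b"]
        if train:
            self._cache = (x.shape, cols, Ho, Wo)
        return out.reshape(x.shape[0], Ho, Wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols, Ho, Wo = self._cache
        B, C, H, W = x_shape
        k, s, p = self.k, self.stride, self.pad
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(
            B * Ho * Wo, self.out_ch
        )
        Wmat = self.params["W"].reshape(self.out_ch, -1)
        cols2 = cols.reshape(B * Ho * Wo, -1)
        self.grads["W"] += (dy2.T @ cols2).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] += dy2.sum(axis=0)
        dcols = (dy2 @ Wmat).reshape(B, Ho * Wo, C * k * k)
        dcols = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n_ch, dtype=np.float32)
        self.params["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.grads["gamma"] = np.zeros(n_ch, dtype=np.float32)
        self.grads["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.params["gamma"]
        b = self.params["beta"]
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float32)
            var = np.einsum("bchw,bchw->c", x, x, optimize=True) / (
                x.shape[0] * x.shape[2] * x.shape[3]
            ) - mean * mean
            var = np.maximum(var, 0.0).astype(np.float32)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        # fused affine: out = x * scale + shift  (two passes over x)
        scale = (g * inv_std).astype(np.float32)
        shift = (b - mean * scale).astype(np.float32)
        out = x * scale[None, :, None, None] + shift[None, :, None, None]
        if train:
            self._cache = (x, mean, inv_std)
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mean, inv_std = self._cache
        B, C, H, W = dy.shape
        m = B * H * W
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.tanh(x)
        if train:
            self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._out**2)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._out * (1.0 - self._out)


class Identity(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0) -> None:
        super().__init__()
        self.k = kernel
        self.stride = stride or kernel
        self.pad = pad

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        B, C, H, W = xp.shape
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        win = win.reshape(B, C, Ho, Wo, k * k)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx, Ho, Wo)
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, idx, Ho, Wo = self._cache
        B, C, H, W = x_shape
        k, s, p = self.k, self.stride, self.pad
        dwin = np.zeros((B, C, Ho, Wo, k * k), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        dwin = dwin.reshape(B, C, Ho, Wo, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dwin[:, :, :, :, i, j]
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class AvgPool2d(Layer):
    """Non-overlapping average pooling (kernel == stride)."""

    def __init__(self, kernel: int) -> None:
        super().__init__()
        self.k = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        B, C, H, W = x.shape
        if H % k or W % k:
            raise ValueError(f"spatial dims {(H, W)} not divisible by pool {k}")
        out = x.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))
        if train:
            self._shape = x.shape
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        B, C, H, W = self._shape
        return np.repeat(np.repeat(dy, k, axis=2), k, axis=3).astype(np.float32) / (k * k)


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C): the image-embedding layer."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        return (np.broadcast_to(dy[:, :, None, None], (B, C, H, W)) / (H * W)).astype(
            np.float32
        )


class Linear(Layer):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator | None = None,
        *,
        w_scale: float | None = None,
        bias_init: float = 0.0,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = w_scale if w_scale is not None else np.sqrt(2.0 / in_dim)
        self.params["W"] = (rng.standard_normal((out_dim, in_dim)) * scale).astype(np.float32)
        self.params["b"] = np.full(out_dim, bias_init, dtype=np.float32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class Embedding(Layer):
    """Lookup table mapping integer ids to dense rows."""

    def __init__(
        self, n_rows: int, dim: int, rng: np.random.Generator | None = None, scale: float = 0.01
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["table"] = (rng.standard_normal((n_rows, dim)) * scale).astype(np.float32)
        self.grads["table"] = np.zeros_like(self.params["table"])

    def forward(self, ids: np.ndarray, train: bool = False) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.ndim != 1:
            raise ValueError("reader ids must be a 1-D integer array")
        n = self.params["table"].shape[0]
        if np.any(ids < 0) or np.any(ids >= n):
            raise IndexError(f"reader id out of range [0, {n})")
        if train:
            self._ids = ids
        return self.params["table"][ids]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        np.add.at(self.grads["table"], self._ids, dy)
        return dy  # no meaningful input gradient


class Dropout(Layer):
    """Inverted dropout on dense activations; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, ResidualBlock)):
                yield from layer.iter_layers()
            else:
                yield layer

    def zero_grad(self) -> None:
        for layer in self.iter_layers():
            layer.zero_grad()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.iter_layers())


class ResidualBlock(Layer):
    """Residual unit: out = relu(main(x) + shortcut(x))."""

    def __init__(self, main: Sequential, shortcut: Layer | None = None) -> None:
        super().__init__()
        self.main = main
        self.shortcut = shortcut or Identity()
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.relu.forward(
            self.main.forward(x, train=train) + self.shortcut.forward(x, train=train),
            train=train,
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        return self.main.backward(d) + self.shortcut.backward(d)

    def iter_layers(self):
        yield from self.main.iter_layers()
        if not isinstance(self.shortcut, Identity):
            if isinstance(self.shortcut, Sequential):
                yield from self.shortcut.iter_layers()
            else:
                yield self.shortcut
        yield self.relu


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    targets = np.asarray(targets, dtype=np.int64)
    loss = float(-np.log(np.clip(probs[np.arange(n), targets], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class SGD:
    """SGD with momentum and per-group learning rates / weight decays.

    ``groups`` maps a group name to ``(layers, lr, weight_decay)``.  The
    effective learning rate for a step is ``lr * lr_scale`` (the schedule
    passes the scale).  Weight decay is coupled L2 (added to the gradient).
    """

    def __init__(
        self, groups: dict[str, tuple[list[Layer], float, float]], momentum: float = 0.9
    ) -> None:
        self.groups = groups
        self.momentum = momentum
        self._velocity: dict[tuple[int, str], np.ndarray] = {}

    def zero_grad(self) -> None:
        for layers, _, _ in self.groups.values():
            for layer in layers:
                layer.zero_grad()

    def step(self, lr_scales: dict[str, float] | float = 1.0) -> None:
        for name, (layers, lr, wd) in self.groups.items():
            scale = lr_scales if isinstance(lr_scales, (int, float)) else lr_scales.get(name, 1.0)
            eff_lr = lr * scale
            for layer in layers:
                for pname, p in layer.params.items():
                    g = layer.grads[pname]
                    if wd:
                        g = g + wd * p
                    key = (id(layer), pname)
                    v = self._velocity.get(key)
                    if v is None:
                        v = np.zeros_like(p)
                    v = self.momentum * v - eff_lr * g
                    self._velocity[key] = v
                    p += v
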