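"""Minimal channel-last layer library with explicit backpropagation.

Everything runs in numpy on a single CPU, which keeps training bit-
deterministic for a fixed seed.  Tensor conventions: 3-D feature maps are
(N, H, W, D, C) with D the spectral depth, 2-D maps are (N, H, W, C).
Convolutions are valid-mode cross-correlations (no padding), matching the
reference definition of the 3-D convolution used by the model.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv3D", "Conv2D", "Dense", "ReLU", "BatchNorm",
    "GlobalAttention", "SqueezeExcite", "MergeDepth", "Flatten", "Adam",
]


class Layer:
    """Base layer: ``params``/``grads`` dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Conv3D(Layer):
    """Valid-mode 3-D convolution over (H, W, D) with channels last."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw, kd = kernel
        self.kernel = kernel
        fan_in = kh * kw * kd * in_channels
        self.params["w"] = _he_init(rng, (kh, kw, kd, in_channels, out_channels), fan_in)
        self.params["b"] = np.zeros(out_channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        kh, kw, kd = self.kernel
        if any(s < k for s, k in zip(x.shape[1:4], self.kernel)):
            raise ValueError(f"kernel {self.kernel} larger than volume {x.shape[1:4]}")
        win = sliding_window_view(x, (kh, kw, kd), axis=(1, 2, 3))
        # win: (N, H', W', D', C_in, kh, kw, kd)
        win = np.ascontiguousarray(win)
        out = np.einsum("nhwdcijk,ijkco->nhwdo", win, self.params["w"],
                        optimize=True) + self.params["b"]
        if train:
            self._win = win
            self._x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw, kd = self.kernel
        self.grads["w"] = np.einsum("nhwdcijk,nhwdo->ijkco", self._win, grad,
                                    optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 1, 2, 3))
        dx = np.zeros(self._x_shape)
        n, ho, wo, do, _ = grad.shape
        w = self.params["w"]
        for i in range(kh):
            for j in range(kw):
                for k in range(kd):
                    dx[:, i:i + ho, j:j + wo, k:k + do, :] += np.einsum(
                        "nhwdo,co->nhwdc", grad, w[i, j, k], optimize=True)
        self._win = None
        return dx


class Conv2D(Layer):
    """Valid-mode 2-D convolution over (H, W) with channels last."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        self.kernel = kernel
        fan_in = kh * kw * in_channels
        self.params["w"] = _he_init(rng, (kh, kw, in_channels, out_channels), fan_in)
        self.params["b"] = np.zeros(out_channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        kh, kw = self.kernel
        if x.shape[1] < kh or x.shape[2] < kw:
            raise ValueError(f"kernel {self.kernel} larger than map {x.shape[1:3]}")
        win = np.ascontiguousarray(sliding_window_view(x, (kh, kw), axis=(1, 2)))
        out = np.einsum("nhwcij,ijco->nhwo", win, self.params["w"],
                        optimize=True) + self.params["b"]
        if train:
            self._win = win
            self._x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        self.grads["w"] = np.einsum("nhwcij,nhwo->ijco", self._win, grad,
                                    optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 1, 2))
        dx = np.zeros(self._x_shape)
        n, ho, wo, _ = grad.shape
        w = self.params["w"]
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + ho, j:j + wo, :] += np.einsum(
                    "nhwo,co->nhwc", grad, w[i, j], optimize=True)
        self._win = None
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _he_init(rng, (in_features, out_features), in_features)
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes (channels last)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std, axes, x.size // x.shape[-1])
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, m = self._cache
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        dxhat = grad * self.params["gamma"]
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _ChannelGate(Layer):
    """Shared squeeze -> bottleneck -> sigmoid -> rescale machinery.

    Pools the input over all axes between batch and channel, passes the
    pooled vector through a two-layer bottleneck with ReLU then sigmoid, and
    multiplies the input by the resulting per-channel gate.  With all gate
    weights and biases at zero the gate is exactly sigmoid(0) = 0.5, so the
    block halves its input — a useful analytic anchor for tests.
    """

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator | None):
        super().__init__()
        if rng is None:
            self.params["w1"] = np.zeros((channels, hidden))
            self.params["w2"] = np.zeros((hidden, channels))
        else:
            self.params["w1"] = _he_init(rng, (channels, hidden), channels)
            self.params["w2"] = _he_init(rng, (hidden, channels), hidden)
        self.params["b1"] = np.zeros(hidden)
        self.params["b2"] = np.zeros(channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        pool_axes = tuple(range(1, x.ndim - 1))
        g = x.mean(axis=pool_axes)
        h1 = np.maximum(g @ self.params["w1"] + self.params["b1"], 0.0)
        gate = _sigmoid(h1 @ self.params["w2"] + self.params["b2"])
        shape = (x.shape[0],) + (1,) * (x.ndim - 2) + (x.shape[-1],)
        out = x * gate.reshape(shape)
        if train:
            self._cache = (x, g, h1, gate, pool_axes, shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, g, h1, gate, pool_axes, shape = self._cache
        dx = grad * gate.reshape(shape)
        dgate = (grad * x).sum(axis=pool_axes)
        dz2 = dgate * gate * (1.0 - gate)
        self.grads["w2"] = h1.T @ dz2
        self.grads["b2"] = dz2.sum(axis=0)
        dh1 = dz2 @ self.params["w2"].T
        dz1 = dh1 * (h1 > 0)
        self.grads["w1"] = g.T @ dz1
        self.grads["b1"] = dz1.sum(axis=0)
        dg = dz1 @ self.params["w1"].T
        m = int(np.prod([x.shape[a] for a in pool_axes]))
        dx += dg.reshape(shape) / m
        self._cache = None
        return dx

    @property
    def gate_weights(self):
        return self.params


class GlobalAttention(_ChannelGate):
    """Channel attention over a 3-D feature map (N, H, W, D, C).

    Global average pooling over H, W and D leaves one value per channel; a
    C -> C/2 -> C bottleneck with sigmoid output produces the attention map
    that rescales each channel of the input.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__(channels, max(1, channels // 2), rng)


class SqueezeExcite(_ChannelGate):
    """Squeeze-and-excitation over a 2-D feature map (N, H, W, C)."""

    def __init__(self, channels: int, reduction: int = 2,
                 rng: np.random.Generator | None = None):
        if channels % reduction != 0:
            raise ValueError("reduction must divide the channel count")
        super().__init__(channels, channels // reduction, rng)


class MergeDepth(Layer):
    """(N, H, W, D, C) -> (N, H, W, D*C): fold spectral depth into channels."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        n, h, w, d, c = x.shape
        return x.reshape(n, h, w, d * c)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for key, param in layer.params.items():
                g = layer.grads[key]
                m[key] = self.beta1 * m[key] + (1 - self.beta1) * g
                v[key] = self.beta2 * v[key] + (1 - self.beta2) * g * g
                mhat = m[key] / b1t
                vhat = v[key] / b2t
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
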