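"""The hybrid 3-D/2-D convolutional protein network and its training loop.

The architecture follows the HybridSN pattern: three valid-mode 3-D
convolutions learn joint spatial-spectral features from a (32 x 32 x D)
patch, the spectral depth is folded into channels, one 2-D convolution
refines spatial structure, and two dense layers feed a linear head
(regression, percent protein) or a softmax head (low/medium/high classes).
Two attentive variants insert a global channel-attention block after the
3-D stack and additionally a squeeze-and-excitation block after the 2-D
convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate

from .layers import (
    Adam,
    BatchNorm,
    Conv2D,
    Conv3D,
    Dense,
    Flatten,
    GlobalAttention,
    MergeDepth,
    ReLU,
    SqueezeExcite,
)

__all__ = [
    "KernelSet", "KERNEL_SETS", "ArchitectureSpec", "TrainConfig",
    "Network", "build_model", "train", "predict", "conv3d_reference",
]


@dataclass(frozen=True)
class KernelSet:
    """The three 3-D kernel shapes of the conv stack, (kh, kw, kd) each."""

    layer1: tuple[int, int, int]
    layer2: tuple[int, int, int]
    layer3: tuple[int, int, int]

    def __post_init__(self) -> None:
        for k in (self.layer1, self.layer2, self.layer3):
            if len(k) != 3 or any(d <= 0 for d in k):
                raise ValueError("kernel shapes must be three positive dims")

    @property
    def shapes(self):
        return (self.layer1, self.layer2, self.layer3)


# the three documented kernel-size sets (spatial x spatial x spectral)
KERNEL_SETS = {
    1: KernelSet((3, 3, 7), (3, 3, 5), (3, 3, 3)),
    2: KernelSet((3, 3, 11), (3, 3, 9), (3, 3, 7)),
    3: KernelSet((5, 5, 15), (5, 5, 11), (5, 5, 9)),
    # compact set for shallow spectral depths (e.g. K = 8 after PCA)
    "compact": KernelSet((3, 3, 3), (3, 3, 3), (3, 3, 3)),
}

_VARIANTS = ("base", "global_attention", "global_attention_se")


@dataclass
class ArchitectureSpec:
    """Declarative description of one network variant."""

    variant: str = "base"
    kernel_set: KernelSet | int | str = 1
    conv3d_filters: tuple[int, int, int] = (8, 16, 32)
    conv2d_filters: int = 64
    conv2d_kernel: tuple[int, int] = (3, 3)
    dense_units: tuple[int, int] = (256, 128)
    task: str = "regression"
    n_classes: int = 3
    se_reduction: int = 2
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if not isinstance(self.kernel_set, KernelSet):
            self.kernel_set = KERNEL_SETS[self.kernel_set]


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 30
    loss: str = "mse"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "categorical_cross_entropy"):
            raise ValueError("loss must be 'mse' or 'categorical_cross_entropy'")


class Network:
    """A feed-forward stack of layers with a task-specific head."""

    def __init__(self, layers, arch: ArchitectureSpec, input_shape):
        self.layers = layers
        self.arch = arch
        self.input_shape = input_shape  # (H, W, D)
        self.y_mean = 0.0
        self.y_std = 1.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)


def _out_after(size: int, kernel: int) -> int:
    return size - kernel + 1


def build_model(arch: ArchitectureSpec, input_depth: int,
                input_hw: tuple[int, int] = (32, 32),
                rng_seed: int = 0) -> Network:
    """Assemble the network and validate that the conv stack fits the input.

    Valid convolutions shrink each axis by (kernel - 1); the spectral depth
    after the three 3-D layers and the spatial extent after the 2-D layer
    must stay >= 1, otherwise the kernel set is incompatible with the input
    and a ValueError is raised.
    """
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 101)))
    h, w = input_hw
    d = input_depth
    layers: list = []
    in_ch = 1
    for filters, kernel in zip(arch.conv3d_filters, arch.kernel_set.shapes):
        kh, kw, kd = kernel
        h2, w2, d2 = _out_after(h, kh), _out_after(w, kw), _out_after(d, kd)
        if min(h2, w2, d2) < 1:
            raise ValueError(
                f"kernel {kernel} exhausts the volume ({h}x{w}x{d})"
            )
        layers.append(Conv3D(in_ch, filters, kernel, rng))
        if arch.batch_norm:
            layers.append(BatchNorm(filters))
        layers.append(ReLU())
        h, w, d, in_ch = h2, w2, d2, filters

    if arch.variant in ("global_attention", "global_attention_se"):
        layers.append(GlobalAttention(in_ch, rng))

    layers.append(MergeDepth())
    ch2d = d * in_ch
    kh, kw = arch.conv2d_kernel
    h2, w2 = _out_after(h, kh), _out_after(w, kw)
    if min(h2, w2) < 1:
        raise ValueError("2-D kernel exhausts the spatial extent")
    layers.append(Conv2D(ch2d, arch.conv2d_filters, arch.conv2d_kernel, rng))
    if arch.batch_norm:
        layers.append(BatchNorm(arch.conv2d_filters))
    layers.append(ReLU())
    h, w, in_ch = h2, w2, arch.conv2d_filters

    if arch.variant == "global_attention_se":
        layers.append(SqueezeExcite(in_ch, arch.se_reduction, rng))

    layers.append(Flatten())
    features = h * w * in_ch
    for units in arch.dense_units:
        layers.append(Dense(features, units, rng))
        layers.append(ReLU())
        features = units
    head = 1 if arch.task == "regression" else arch.n_classes
    layers.append(Dense(features, head, rng))

    hw = input_hw
    return Network(layers, arch, (hw[0], hw[1], input_depth))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _as_input(patches: np.ndarray) -> np.ndarray:
    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 4:  # (N, H, W, D) -> add singleton channel
        patches = patches[..., None]
    if patches.ndim != 5:
        raise ValueError("patches must be (N, H, W, D) or (N, H, W, D, C)")
    return patches


def train(model: Network, patches: np.ndarray, targets: np.ndarray,
          config: TrainConfig) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss history.

    Regression targets are standardized internally (and predictions mapped
    back), which keeps the MSE loss well-scaled regardless of the percent
    units; classification targets are integer class indices trained with
    softmax cross-entropy.
    """
    x = _as_input(patches)
    if model.arch.task == "regression":
        if config.loss != "mse":
            raise ValueError("regression task requires the mse loss")
        y = np.asarray(targets, dtype=float).reshape(-1)
        model.y_mean = float(y.mean())
        model.y_std = float(y.std()) or 1.0
        y_scaled = (y - model.y_mean) / model.y_std
    else:
        if config.loss != "categorical_cross_entropy":
            raise ValueError("classification task requires categorical_cross_entropy")
        y = np.asarray(targets)
        if y.ndim == 2:  # one-hot -> indices
            y = y.argmax(axis=1)
        y = y.astype(int)
    if len(x) != len(y):
        raise ValueError("patch and target counts differ")

    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 7)))
    optimizer = Adam(model.layers, lr=config.learning_rate)
    history: list[float] = []
    n = len(x)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            out = model.forward(x[idx], train=True)
            if model.arch.task == "regression":
                resid = out[:, 0] - y_scaled[idx]
                loss = float(np.mean(resid ** 2))
                grad = (2.0 / len(idx)) * resid[:, None]
            else:
                probs = _softmax(out)
                eps = 1e-12
                loss = float(-np.mean(np.log(probs[np.arange(len(idx)), y[idx]] + eps)))
                grad = probs.copy()
                grad[np.arange(len(idx)), y[idx]] -= 1.0
                grad /= len(idx)
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def predict(model: Network, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Predicted percent protein (regression) or class-probability rows."""
    x = _as_input(patches)
    outs = []
    for start in range(0, len(x), batch_size):
        out = model.forward(x[start:start + batch_size], train=False)
        if model.arch.task == "regression":
            outs.append(out[:, 0] * model.y_std + model.y_mean)
        else:
            outs.append(_softmax(out))
    return np.concatenate(outs, axis=0)


def conv3d_reference(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Reference valid-mode 3-D convolution (cross-correlation form).

    F(x, y, z) = sum_{i,j,k} V(x+i, y+j, z+k) * K(i, j, k); output dims are
    input - kernel + 1 per axis.
    """
    volume = np.asarray(volume, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if volume.ndim != 3 or kernel.ndim != 3:
        raise ValueError("volume and kernel must be 3-D")
    if any(v < k for v, k in zip(volume.shape, kernel.shape)):
        raise ValueError("kernel larger than volume")
    return correlate(volume, kernel, mode="valid")
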