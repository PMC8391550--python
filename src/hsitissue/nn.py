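"""A compact numpy neural-network engine for small 3-D convolutional models.

The per-pixel classifier here is tiny (tens of thousands of parameters, inputs of
5 x 5 x 100), so a vectorized im2col implementation on the CPU is entirely
adequate: each convolution is one matrix multiply per batch. The engine provides
exactly what the tissue-recognition CNN needs and nothing more: 3-D convolution
layers with spectral striding, ReLU, fully connected layers, class-weighted
softmax cross-entropy and Adam.

Array layout is ``(N, C, D, H, W)`` with ``D`` the spectral axis; all math is
float32. Initialization is uniform fan-in (weights and biases drawn from
``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``), seeded, so training is bit-reproducible
for a fixed seed and data order.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv3d:
    """3-D convolution with per-axis stride and zero padding, plus bias."""

    def __init__(self, in_channels, out_channels, kernel, stride=(1, 1, 1), padding=(0, 0, 0)):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        fan_in = in_channels * int(np.prod(self.kernel))
        self._fan_in = fan_in
        self.weight = np.zeros((out_channels, fan_in), dtype=np.float32)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self._cache = None

    def initialize(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(self._fan_in)
        self.weight = rng.uniform(-bound, bound, self.weight.shape).astype(np.float32)
        self.bias = rng.uniform(-bound, bound, self.bias.shape).astype(np.float32)

    def out_shape(self, in_shape: tuple) -> tuple:
        d, h, w = in_shape
        out = []
        for size, k, s, p in zip((d, h, w), self.kernel, self.stride, self.padding):
            o = (size + 2 * p - k) // s + 1
            if o < 1:
                raise ValueError(
                    f"conv kernel {self.kernel} stride {self.stride} collapses input {in_shape}"
                )
            out.append(o)
        return tuple(out)

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        pd, ph, pw = self.padding
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw]
        od, oh, ow = win.shape[2:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n, od * oh * ow, -1
        )
        y = cols @ self.weight.T + self.bias
        if train:
            self._cache = (x.shape, cols, (od, oh, ow))
        return np.ascontiguousarray(y.reshape(n, od, oh, ow, -1).transpose(0, 4, 1, 2, 3))

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        x_shape, cols, (od, oh, ow) = self._cache
        n, c, d, h, w = x_shape
        pd, ph, pw = self.padding
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        dyr = dy.transpose(0, 2, 3, 4, 1).reshape(n, od * oh * ow, self.out_channels)
        self.grad_weight = dyr.reshape(-1, self.out_channels).T @ cols.reshape(
            -1, cols.shape[-1]
        )
        self.grad_bias = dyr.sum(axis=(0, 1))
        if not need_dx:
            self._cache = None
            return None
        dcols = (dyr @ self.weight).reshape(n, od, oh, ow, c, kd, kh, kw)
        dxp = np.zeros((n, c, d + 2 * pd, h + 2 * ph, w + 2 * pw), dtype=np.float32)
        for a in range(kd):
            for b in range(kh):
                for g in range(kw):
                    dxp[
                        :,
                        :,
                        a : a + sd * od : sd,
                        b : b + sh * oh : sh,
                        g : g + sw * ow : sw,
                    ] += dcols[:, :, :, :, :, a, b, g].transpose(0, 4, 1, 2, 3)
        self._cache = None
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]

    def parameters(self):
        yield "weight", self
        yield "bias", self


class ReLU:
    n_params = 0

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Flatten:
    n_params = 0

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense:
    """Fully connected layer."""

    def __init__(self, in_features, out_features):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = np.zeros((out_features, in_features), dtype=np.float32)
        self.bias = np.zeros(out_features, dtype=np.float32)

    def initialize(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(self.in_features)
        self.weight = rng.uniform(-bound, bound, self.weight.shape).astype(np.float32)
        self.bias = rng.uniform(-bound, bound, self.bias.shape).astype(np.float32)

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, dy):
        self.grad_weight = dy.T @ self._x
        self.grad_bias = dy.sum(axis=0)
        return dy @ self.weight


class Network:
    """A plain layer stack with seeded initialization."""

    def __init__(self, layers: list, seed: int = 0):
        self.layers = layers
        rng = np.random.default_rng(seed)
        for layer in layers:
            if hasattr(layer, "initialize"):
                layer.initialize(rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        for i, layer in enumerate(reversed(self.layers)):
            if i == len(self.layers) - 1 and isinstance(layer, Conv3d):
                return layer.backward(dy, need_dx=False)
            dy = layer.backward(dy)
        return dy

    def trainable_layers(self):
        return [l for l in self.layers if getattr(l, "n_params", 0) > 0]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def state(self) -> dict:
        out = {}
        for i, layer in enumerate(self.trainable_layers()):
            out[f"w{i}"] = layer.weight.copy()
            out[f"b{i}"] = layer.bias.copy()
        return out

    def load_state(self, state: dict) -> None:
        for i, layer in enumerate(self.trainable_layers()):
            layer.weight = state[f"w{i}"].astype(np.float32).reshape(layer.weight.shape)
            layer.bias = state[f"b{i}"].astype(np.float32).reshape(layer.bias.shape)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> tuple:
    """Class-weighted softmax cross-entropy.

    ``loss = sum_i w[y_i] * (-log softmax(logits_i)[y_i]) / sum_i w[y_i]`` —
    the weighted-mean convention, so the loss scale is independent of the batch's
    class composition. Returns ``(loss, dlogits)``; labels are 0-based indices.
    """
    logits = logits.astype(np.float64)
    shifted = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    log_probs = shifted - logsumexp
    n = len(labels)
    w = class_weights[labels]
    wsum = w.sum()
    loss = -(w * log_probs[np.arange(n), labels]).sum() / wsum
    grad = np.exp(log_probs)
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / wsum)[:, None]
    return float(loss), grad.astype(np.float32)


class Adam:
    """Adam optimizer over a network's trainable layers."""

    def __init__(self, network: Network, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for i, layer in enumerate(network.trainable_layers()):
            for name in ("weight", "bias"):
                key = (i, name)
                self._m[key] = np.zeros_like(getattr(layer, name), dtype=np.float64)
                self._v[key] = np.zeros_like(getattr(layer, name), dtype=np.float64)

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, layer in enumerate(self.network.trainable_layers()):
            for name in ("weight", "bias"):
                grad = getattr(layer, f"grad_{name}").astype(np.float64)
                key = (i, name)
                self._m[key] = self.beta1 * self._m[key] + (1 - self.beta1) * grad
                self._v[key] = self.beta2 * self._v[key] + (1 - self.beta2) * grad**2
                update = (
                    self.lr * (self._m[key] / b1t) / (np.sqrt(self._v[key] / b2t) + self.eps)
                )
                setattr(
                    layer,
                    name,
                    (getattr(layer, name).astype(np.float64) - update).astype(np.float32),
                )
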