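"""Minimal dense/convolutional network layers with manual backprop.

Small fully-connected and 1D-convolutional building blocks sized for the
low-capacity regime this package operates in (hundreds of labeled peptides,
tiny policy/value networks).  Everything is plain numpy: layers expose
``forward`` returning ``(output, cache)`` and ``backward`` consuming the
upstream gradient and cache while accumulating parameter gradients.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: layers hold ``params`` and matching ``grads`` lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        # He initialization, suitable for the ReLU blocks used throughout
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x @ self.W + self.b, x

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> np.ndarray:
        x = cache
        self.grads[0] += x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class Conv1D(Layer):
    """Valid (no-padding) 1D convolution over (batch, length, channels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        self.k = kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / (c_in * kernel)), size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b, length, _ = x.shape
        l_out = length - self.k + 1
        y = np.broadcast_to(self.b, (b, l_out, self.b.shape[0])).copy()
        for dt in range(self.k):
            y += x[:, dt : dt + l_out, :] @ self.W[dt]
        return y, x

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> np.ndarray:
        x = cache
        l_out = dy.shape[1]
        dx = np.zeros_like(x)
        for dt in range(self.k):
            x_slice = x[:, dt : dt + l_out, :]
            self.grads[0][dt] += np.einsum("blc,blo->co", x_slice, dy)
            dx[:, dt : dt + l_out, :] += dy @ self.W[dt].T
        self.grads[1] += dy.sum(axis=(0, 1))
        return dx


class ReLU(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = x > 0
        return x * mask, mask

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> np.ndarray:
        return dy * cache


class Dropout(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        if not train or self.p <= 0:
            return x, np.ones_like(x)
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> np.ndarray:
        return dy * cache


class GlobalMaxPool(Layer):
    """Max over the length axis of (batch, length, channels)."""

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        idx = x.argmax(axis=1)
        b, _, c = x.shape
        return x[np.arange(b)[:, None], idx, np.arange(c)[None, :]], (idx, x.shape)

    def backward(self, dy: np.ndarray, cache: tuple) -> np.ndarray:
        idx, shape = cache
        dx = np.zeros(shape)
        b, _, c = shape
        np.add.at(dx, (np.arange(b)[:, None], idx, np.arange(c)[None, :]), dy)
        return dx


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.pairs = [
            (p, g) for layer in layers for p, g in zip(layer.params, layer.grads)
        ]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def parameter_vector(layers: list[Layer]) -> np.ndarray:
    """Flat copy of all parameters (for hashing / equality checks)."""
    parts = [p.ravel() for layer in layers for p in layer.params]
    return np.concatenate(parts) if parts else np.zeros(0)


def mlp(sizes: list[int], rng: np.random.Generator) -> list[Layer]:
    """Dense-ReLU stack ending in a linear layer."""
    layers: list[Layer] = []
    for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
        layers.append(Dense(a, b, rng))
        if i < len(sizes) - 2:
            layers.append(ReLU())
    return layers


def mlp_forward(layers: list[Layer], x: np.ndarray) -> tuple[np.ndarray, list]:
    caches = []
    for layer in layers:
        x, c = layer.forward(x)
        caches.append(c)
    return x, caches


def mlp_backward(layers: list[Layer], dy: np.ndarray, caches: list) -> np.ndarray:
    for layer, c in zip(reversed(layers), reversed(caches)):
        dy = layer.backward(dy, c)
    return dy
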