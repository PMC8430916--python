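"""Minimal NumPy neural-network engine for the retention-index base models.

Implements exactly the layers the base regressors need — dense layers with
residual additions, 1-D convolutions over the SMILES one-hot grid, global
average pooling — with manual backpropagation and an Adam optimizer.  All
math is float32.  Nets expose flat parameter lists so that weights trained on
one task can initialize another (transfer learning) with shape checking.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Conv1D:
    """Same-padded 1-D convolution over (batch, length, channels) tensors."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, stride: int = 1):
        self.kernel, self.stride, self.c_in, self.c_out = kernel, stride, c_in, c_out
        self.W = _he_init(rng, (kernel * c_in, c_out), kernel * c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._idx = None
        self._l_pad = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def _gather_index(self, length: int) -> np.ndarray:
        pad = self.kernel // 2
        l_out = (length + 2 * pad - self.kernel) // self.stride + 1
        starts = np.arange(l_out) * self.stride
        return starts[:, None] + np.arange(self.kernel)[None, :]  # into padded axis

    def forward(self, x: np.ndarray) -> np.ndarray:
        batch, length, _ = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        idx = self._gather_index(length)
        cols = xp[:, idx, :].reshape(batch, idx.shape[0], self.kernel * self.c_in)
        self._cols, self._idx, self._l_pad = cols, idx, xp.shape[1]
        return cols @ self.W + self.b

    def backward(self, g: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        batch, l_out, _ = g.shape
        cols2 = self._cols.reshape(batch * l_out, -1)
        self.dW[...] = cols2.T @ g.reshape(batch * l_out, self.c_out)
        self.db[...] = g.sum(axis=(0, 1))
        if not need_input_grad:
            return None
        # scatter-add column gradients back onto the padded input axis
        dcols = (g @ self.W.T).reshape(batch, l_out, self.kernel, self.c_in)
        dxp = np.zeros((self._l_pad, batch, self.c_in), dtype=np.float32)
        flat_idx = self._idx.reshape(-1)
        np.add.at(dxp, flat_idx, dcols.transpose(1, 2, 0, 3).reshape(len(flat_idx), batch, self.c_in))
        pad = self.kernel // 2
        return dxp[pad:self._l_pad - pad].transpose(1, 0, 2)


class GlobalAvgPool:
    """Mean over the length axis of (batch, length, channels)."""

    def __init__(self):
        self._length = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(g[:, None, :] / self._length, self._length, axis=1)


class Adam:
    """Adam over a list of parameter arrays (updates in place)."""

    def __init__(self, params, grads, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class MLPNet:
    """Residual multilayer perceptron: descriptors + phase encoding -> scaled RI."""

    def __init__(self, rng, n_in: int, width: int, n_blocks: int):
        self.input = Dense(rng, n_in, width)
        self.in_act = ReLU()
        self.blocks = [Dense(rng, width, width) for _ in range(n_blocks)]
        self.block_acts = [ReLU() for _ in range(n_blocks)]
        self.head = Dense(rng, width, 1)
        self.layers = [self.input] + self.blocks + [self.head]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.in_act.forward(self.input.forward(x))
        for dense, act in zip(self.blocks, self.block_acts):
            h = h + act.forward(dense.forward(h))
        return self.head.forward(h)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        g = self.head.backward(dy[:, None])
        for dense, act in zip(reversed(self.blocks), reversed(self.block_acts)):
            g = g + dense.backward(act.backward(g))
        self.input.backward(self.in_act.backward(g))


class CNNNet:
    """1-D convolutional net over the SMILES one-hot grid, merged with the
    phase encoding before the dense head."""

    def __init__(self, rng, alphabet: int, sp_dim: int, c1: int, c2: int,
                 kernel: int, dense_width: int):
        self.conv1 = Conv1D(rng, alphabet, c1, kernel, stride=1)
        self.act1 = ReLU()
        self.conv2 = Conv1D(rng, c1, c2, kernel, stride=2)
        self.act2 = ReLU()
        self.pool = GlobalAvgPool()
        self.merge = Dense(rng, c2 + sp_dim, dense_width)
        self.merge_act = ReLU()
        self.head = Dense(rng, dense_width, 1)
        self.layers = [self.conv1, self.conv2, self.merge, self.head]
        self._c2 = c2

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, grid: np.ndarray, sp: np.ndarray) -> np.ndarray:
        z = self.act1.forward(self.conv1.forward(grid))
        z = self.act2.forward(self.conv2.forward(z))
        pooled = self.pool.forward(z)
        h = np.concatenate([pooled, sp], axis=1)
        return self.head.forward(self.merge_act.forward(self.merge.forward(h)))[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        g = self.head.backward(dy[:, None])
        g = self.merge.backward(self.merge_act.backward(g))
        g_pool = g[:, : self._c2]
        g = self.pool.backward(g_pool)
        g = self.conv2.backward(self.act2.backward(g))
        self.conv1.backward(self.act1.backward(g), need_input_grad=False)


def get_params(net) -> list[np.ndarray]:
    """Copies of all parameter arrays, in a stable order."""
    return [p.copy() for p in net.params]


def set_params(net, values: list[np.ndarray]) -> None:
    """Load parameter arrays into a net; shapes must match exactly."""
    current = net.params
    if len(values) != len(current):
        raise ValueError(f"expected {len(current)} arrays, got {len(values)}")
    for p, v in zip(current, values):
        if p.shape != v.shape:
            raise ValueError(f"parameter shape mismatch: {p.shape} vs {v.shape}")
        p[...] = v.astype(np.float32)


def parameter_count(net) -> int:
    return sum(p.size for p in net.params)
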