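"""Minimal 1-D convolutional network engine in NumPy.

Implements exactly the layer vocabulary needed by the tremor/context
classifiers: 1-D convolution with "same" padding and ReLU, max pooling,
global average pooling, dense layers, inverted dropout, and sigmoid
classification heads trained with binary cross-entropy and Adam.

Design choices mirror common Keras defaults so that the declarative model
specifications translate one-to-one: Glorot-uniform weight init, zero bias
init, "same" padding with the extra sample on the right, Adam with
beta1=0.9, beta2=0.999, eps=1e-7.

All randomness (init, shuffling, dropout) flows through a single
``numpy.random.Generator``, so identical seeds give identical weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1D", "MaxPool1D", "GlobalAveragePool", "Dense", "Dropout", "Network", "Adam"]


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1D:
    """1-D convolution over (batch, length, channels) with 'same' padding.

    Weights are stored as (kernel * in_channels, filters) so the forward
    pass is an im2col matrix product.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, activation: str = "relu"):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.activation = activation
        fan_in = kernel * in_channels
        fan_out = kernel * filters
        self.W = _glorot_uniform(rng, (fan_in, filters), fan_in, fan_out)
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # 'same' padding: total kernel-1, split left-short / right-long
        self._pad_left = (kernel - 1) // 2
        self._pad_right = kernel - 1 - self._pad_left

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self._pad_left, self._pad_right), (0, 0)))
        # (B, L, C, K) -> (B, L, K, C) -> (B, L, K*C)
        cols = sliding_window_view(xp, self.kernel, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, L, -1)
        z = cols @ self.W + self.b
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
        else:
            out = z
        self._cache = (cols, out, (B, L, C))
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, out, (B, L, C) = self._cache
        if self.activation == "relu":
            gout = gout * (out > 0)
        flat_cols = cols.reshape(B * L, -1)
        flat_g = gout.reshape(B * L, self.filters)
        self.dW[...] = flat_cols.T @ flat_g
        self.db[...] = flat_g.sum(axis=0)
        dcols = (flat_g @ self.W.T).reshape(B, L, self.kernel, C)
        dxp = np.zeros((B, L + self.kernel - 1, C))
        for k in range(self.kernel):
            dxp[:, k:k + L, :] += dcols[:, :, k, :]
        return dxp[:, self._pad_left:self._pad_left + L, :]


class MaxPool1D:
    def __init__(self, size: int = 2):
        self.size = size

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // self.size
        xr = x[:, :Lo * self.size, :].reshape(B, Lo, self.size, C)
        idx = xr.argmax(axis=2)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2).squeeze(2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        idx, (B, L, C) = self._cache
        Lo = L // self.size
        dxr = np.zeros((B, Lo, self.size, C))
        np.put_along_axis(dxr, idx[:, :, None, :], gout[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, :Lo * self.size, :] = dxr.reshape(B, Lo * self.size, C)
        return dx


class GlobalAveragePool:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.repeat(gout[:, None, :], self._L, axis=1) / self._L


class Dense:
    def __init__(self, in_features: int, units: int, rng: np.random.Generator,
                 activation: str = "relu"):
        self.in_features = in_features
        self.units = units
        self.activation = activation
        self.W = _glorot_uniform(rng, (in_features, units), in_features, units)
        self.b = np.zeros(units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        z = x @ self.W + self.b
        out = np.maximum(z, 0.0) if self.activation == "relu" else z
        self._cache = (x, out)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, out = self._cache
        if self.activation == "relu":
            gout = gout * (out > 0)
        self.dW[...] = x.T @ gout
        self.db[...] = gout.sum(axis=0)
        return gout @ self.W.T


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask


class Network:
    """Shared trunk plus one or more head branches, each ending in a
    single-logit dense layer (sigmoid applied at the loss / prediction)."""

    def __init__(self, trunk, branches: dict):
        self.trunk = trunk
        self.branches = branches  # head name -> list of layers (last outputs 1 logit)

    # --- parameter plumbing -------------------------------------------------
    def _layers(self):
        yield from self.trunk
        for branch in self.branches.values():
            yield from branch

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def grads(self):
        out = []
        for layer in self._layers():
            out.extend(layer.grads())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    # --- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> dict:
        h = x
        for layer in self.trunk:
            h = layer.forward(h, train=train, rng=rng)
        logits = {}
        for name, branch in self.branches.items():
            z = h
            for layer in branch:
                z = layer.forward(z, train=train, rng=rng)
            logits[name] = z[:, 0]
        return logits

    def backward(self, dlogits: dict) -> None:
        dtrunk = None
        for name, branch in self.branches.items():
            g = dlogits[name][:, None]
            for layer in reversed(branch):
                g = layer.backward(g)
            dtrunk = g if dtrunk is None else dtrunk + g
        g = dtrunk
        for layer in reversed(self.trunk):
            g = layer.backward(g)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> dict:
        """Sigmoid probabilities per head, chunked to bound memory."""
        outs = {name: [] for name in self.branches}
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start:start + batch_size], train=False)
            for name, z in logits.items():
                outs[name].append(_sigmoid(z))
        return {name: np.concatenate(chunks) for name, chunks in outs.items()}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray):
    """Masked mean binary cross-entropy and its gradient w.r.t. logits.

    Returns (loss, grad); samples where ``mask`` is False contribute
    nothing. If no sample is unmasked the loss and gradient are zero.
    """
    n = int(mask.sum())
    grad = np.zeros_like(logits)
    if n == 0:
        return 0.0, grad
    z = logits[mask]
    y = targets[mask]
    # log(1+exp(-|z|)) form, numerically stable
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad[mask] = (_sigmoid(z) - y) / n
    return loss, grad


class Adam:
    def __init__(self, params, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
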