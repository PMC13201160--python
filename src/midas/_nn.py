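"""Minimal numpy neural-network primitives with explicit backward passes.

Everything needed for the GIN node classifier: linear layers, batch
normalization with running statistics, ReLU, inverted dropout and an Adam
optimizer.  Layers cache their forward activations and expose
``backward(dY)``; parameters and gradients are plain numpy arrays, which
keeps CPU training bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # Glorot-uniform initialization
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @property
    def d_in(self) -> int:
        return self.W.shape[0]

    @property
    def d_out(self) -> int:
        return self.W.shape[1]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"linear layer expects width {self.W.shape[0]}, got {x.shape[1]}"
            )
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm:
    """Per-feature normalization; batch statistics while training, running
    statistics (momentum 0.1) in eval mode."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.dgamma = np.zeros(d)
        self.dbeta = np.zeros(d)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dy.shape[0]
        self.dgamma = (dy * xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def parameters(self):
        return []


class Dropout:
    """Inverted dropout: identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask

    def parameters(self):
        return []


class Adam:
    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        # params: list of (array, grad-getter) pairs resolved at step time
        self._layers = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p) for p, _ in self._pairs()]
        self._v = [np.zeros_like(p) for p, _ in self._pairs()]

    def _pairs(self):
        out = []
        for layer in self._layers:
            out.extend(layer.parameters())
        return out

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self._pairs()):
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
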