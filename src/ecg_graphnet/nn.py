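"""Minimal NumPy neural-network primitives.

Dense layers, batch normalization, graph convolution, ReLU/sigmoid/softmax
and an Adam optimizer — everything the segment autoencoders and the graph
networks need, with hand-written backward passes. All layers operate on
2-D arrays (rows = samples or graph nodes) and are deterministic given a
seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import scipy.sparse as sp

__all__ = [
    "relu",
    "sigmoid",
    "softmax",
    "cross_entropy",
    "glorot_uniform",
    "Dense",
    "BatchNorm",
    "GraphConv",
    "Adam",
    "collect_params",
    "get_state",
    "set_state",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-branch logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of integer ``labels`` under ``probs``."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(p, 1e-12, None))))


def glorot_uniform(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Layer:
    """Base: parameters in ``self.params``, gradients in ``self.grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": glorot_uniform(n_in, n_out, rng), "b": np.zeros(n_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ g
        self.grads["b"] += g.sum(axis=0)
        return g @ self.params["W"].T


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics.

    Training mode normalizes by batch moments and updates running averages;
    inference mode uses the running averages, so a single graph (or a single
    beat) can be normalized without a batch. The default momentum of 1.0
    keeps the running statistics equal to the latest training batch's
    moments — the right choice for full-batch training, where stale
    exponential averages would lag the fast-moving weights; lower it for
    minibatch regimes.
    """

    def __init__(self, n_features: int, momentum: float = 1.0, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.grads["gamma"] += (g * xhat).sum(axis=0)
        self.grads["beta"] += g.sum(axis=0)
        gx = g * self.params["gamma"]
        if not self._train:
            return gx * self._inv_std
        n = g.shape[0]
        return (self._inv_std / n) * (
            n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0)
        )


class GraphConv(Layer):
    """Spectral-style graph convolution ``Z = Â H W + b``.

    ``Â`` is the symmetrically degree-normalized weighted adjacency (with
    self-loops), supplied per forward call so one parameter set serves
    graphs of any size.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": glorot_uniform(n_in, n_out, rng), "b": np.zeros(n_out)}
        self.zero_grad()

    def forward(self, h: np.ndarray, a_hat, train: bool = False) -> np.ndarray:
        self._a_hat = a_hat
        self._ah = a_hat @ h
        return self._ah @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._ah.T @ g
        self.grads["b"] += g.sum(axis=0)
        gh = g @ self.params["W"].T
        return self._a_hat.T @ gh


def normalize_adjacency(a) -> sp.csr_matrix:
    """Return ``D^{-1/2} A D^{-1/2}`` for a weighted adjacency with self-loops.

    Self-loops guarantee strictly positive degrees. Accepts dense or sparse.
    """
    a = sp.csr_matrix(a, dtype=float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("adjacency has a non-positive degree row")
    d = sp.diags(1.0 / np.sqrt(deg))
    return (d @ a @ d).tocsr()


class Adam:
    def __init__(self, layers: Iterable[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** self.t)
                vhat = v[k] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for ly in self.layers:
            ly.zero_grad()


def collect_params(layers: Iterable[Layer]) -> int:
    """Total number of trainable scalars across ``layers``."""
    return sum(int(np.prod(v.shape)) for ly in layers for v in ly.params.values())


def get_state(layers: Iterable[Layer]) -> list[dict]:
    state = []
    for ly in layers:
        s = {"params": {k: v.copy() for k, v in ly.params.items()}}
        if isinstance(ly, BatchNorm):
            s["running_mean"] = ly.running_mean.copy()
            s["running_var"] = ly.running_var.copy()
        state.append(s)
    return state


def set_state(layers: Iterable[Layer], state: list[dict]) -> None:
    for ly, s in zip(layers, state):
        for k, v in s["params"].items():
            ly.params[k] = v.copy()
        if isinstance(ly, BatchNorm):
            ly.running_mean = s["running_mean"].copy()
            ly.running_var = s["running_var"].copy()
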