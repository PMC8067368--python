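"""Small shared NumPy neural-network primitives (activations, Adam, scaling)."""

from __future__ import annotations

import numpy as np

__all__ = ["leaky_relu", "leaky_relu_grad", "sigmoid", "Adam", "Standardizer"]


class DivergenceError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


def leaky_relu(x, a: float = 10.0):
    """x for x > 0, x / a otherwise (divisor parameterization, a > 1)."""
    if a <= 1:
        raise ValueError(f"leaky divisor must be > 1, got {a}")
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    # for a > 1, max(x, x/a) equals the piecewise definition on both branches
    return np.maximum(x, x * (1.0 / a))


def leaky_relu_grad(x, a: float = 10.0):
    x = np.asarray(x)
    one = x.dtype.type(1.0) if np.issubdtype(x.dtype, np.floating) else 1.0
    return np.where(x > 0, one, one / a)


def sigmoid(x):
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class Adam:
    """Plain Adam over a flat list of ndarray parameters (full-batch use)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain full-batch gradient descent (optional alternative to Adam)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4):
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class Standardizer:
    """Per-column mean/SD scaling; zero-variance columns get SD 1."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def make_optimizer(name: str, params: list[np.ndarray], lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer '{name}' (use 'adam' or 'sgd')")
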