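"""Wavelength-importance profiles and probabilistic wavelength sampling.

The core idea: train a dense network on the full preprocessed spectra, read
the first hidden layer's weight matrix W (n_hidden x m), and score each
wavelength b by the attention indicator

    T_b = sum_i |W[i, b]|

A large T_b means the network routes a lot of signal from that wavelength into
the rest of the model. T is normalized to a probability distribution T_nor
(T_b / sum T) and used to sample each ensemble sub-model's input wavelengths —
informative bands are picked often, but every wavelength keeps a chance, which
preserves diversity across sub-models.

The module also provides NIPALS PLS1 and the alternative importance profile
built from absolute PLS regression coefficients (the "regression coefficient"
selector used by the RC ensemble variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpectraSet, fit_target_scaler
from .nnet import (DivergenceError, Standardizer, leaky_relu, leaky_relu_grad,
                   make_optimizer, sigmoid)

__all__ = [
    "AttentionProfile",
    "AttentionConfig",
    "train_attention_ann",
    "weight_indicator",
    "normalize_indicator",
    "sample_wavelengths",
    "PLSModel",
    "nipals_pls_fit",
    "pls_predict",
    "regression_coefficient_profile",
    "select_pls_components",
]


@dataclass(frozen=True)
class AttentionProfile:
    """Per-wavelength importance T and its normalized sampling distribution."""

    T: np.ndarray
    T_nor: np.ndarray
    source: str  # attention_ann | pls_coefficient | uniform_random

    def __post_init__(self) -> None:
        if self.T.shape != self.T_nor.shape or self.T.ndim != 1:
            raise ValueError("T and T_nor must be 1-D and the same length")
        if np.any(self.T_nor < 0) or abs(self.T_nor.sum() - 1.0) > 1e-9:
            raise ValueError("T_nor must be a probability vector")

    @property
    def m(self) -> int:
        return self.T.size

    def to_frame(self, wavelengths=None) -> pd.DataFrame:
        df = pd.DataFrame({"T": self.T, "T_nor": self.T_nor})
        if wavelengths is not None:
            df.insert(0, "wavelength", np.asarray(wavelengths))
        return df


def weight_indicator(W: np.ndarray) -> np.ndarray:
    """Column sums of |W| over hidden nodes: T_b = sum_i |W[i, b]|."""
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("empty weight matrix")
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite weights")
    return np.abs(np.atleast_2d(W)).sum(axis=0)


def normalize_indicator(T: np.ndarray) -> np.ndarray:
    """Normalize a nonnegative indicator to a probability distribution."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("indicator must be nonnegative")
    total = T.sum()
    if total <= 0:
        raise ValueError("degenerate indicator: sum is zero")
    return T / total


def uniform_profile(m: int) -> AttentionProfile:
    T = np.ones(m)
    return AttentionProfile(T=T, T_nor=T / m, source="uniform_random")


@dataclass
class AttentionConfig:
    """Dense attention network: m inputs -> hidden1 -> hidden2 -> 1 sigmoid.

    Hidden activations are LeakyReLU with divisor ``leaky_divisor`` (negative
    inputs divided by it); training is full-batch on standardized X and
    targets affinely scaled into the sigmoid's interior. Only the magnitude
    pattern of the first-layer weights is consumed downstream, so mild
    overfitting is harmless and no regularization is applied.

    The first layer starts near zero (``first_layer_init``) and training uses
    plain gradient descent: |W| then accumulates in proportion to how
    consistently a wavelength's gradient points somewhere, so the indicator
    reflects learned structure instead of the random initialization.
    Adaptive per-coordinate optimizers grow informative and uninformative
    weights at the same rate and flatten the indicator; they remain available
    through ``optimizer`` for experimentation.
    """

    hidden_sizes: tuple[int, int] = (64, 16)
    leaky_divisor: float = 10.0
    learning_rate: float = 2.0
    n_iterations: int = 2000
    optimizer: str = "sgd"
    first_layer_init: float = 1e-3
    seed: int = 0


def train_attention_ann(trainset: SpectraSet,
                        config: AttentionConfig | None = None) -> AttentionProfile:
    """Train the attention network and return its wavelength profile.

    Same config and seed give an identical profile. Raises
    :class:`~nirecnn.nnet.DivergenceError` if the loss goes non-finite and a
    scaler error if the targets are constant.
    """
    if config is None:
        config = AttentionConfig()
    X = trainset.spectra
    n, m = X.shape
    scaler = fit_target_scaler(trainset.targets)  # raises on constant y
    y = scaler.scale(trainset.targets)
    std = Standardizer(X)
    Xs = std.transform(X)

    rng = np.random.default_rng(config.seed)
    h1, h2 = config.hidden_sizes
    a = config.leaky_divisor
    W1 = rng.standard_normal((h1, m)) * config.first_layer_init
    b1 = np.zeros(h1)
    W2 = rng.standard_normal((h2, h1)) * np.sqrt(1.0 / h1)
    b2 = np.zeros(h2)
    W3 = rng.standard_normal((1, h2)) * np.sqrt(1.0 / h2)
    b3 = np.zeros(1)
    params = [W1, b1, W2, b2, W3, b3]
    opt = make_optimizer(config.optimizer, params, config.learning_rate)

    for it in range(config.n_iterations):
        Z1 = Xs @ W1.T + b1
        A1 = leaky_relu(Z1, a)
        Z2 = A1 @ W2.T + b2
        A2 = leaky_relu(Z2, a)
        Z3 = A2 @ W3.T + b3
        P = sigmoid(Z3)[:, 0]

        resid = P - y
        loss = float(np.mean(resid ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(
                f"attention training diverged at iteration {it}")

        dZ3 = (2.0 / n) * resid * P * (1.0 - P)          # (n,)
        dW3 = dZ3 @ A2                                   # (h2,)
        db3 = dZ3.sum()
        dA2 = np.outer(dZ3, W3[0])
        dZ2 = dA2 * leaky_relu_grad(Z2, a)
        dW2 = dZ2.T @ A1
        db2 = dZ2.sum(axis=0)
        dA1 = dZ2 @ W2
        dZ1 = dA1 * leaky_relu_grad(Z1, a)
        dW1 = dZ1.T @ Xs
        db1 = dZ1.sum(axis=0)
        opt.step([dW1, db1, dW2, db2,
                  dW3[None, :], np.array([db3])])

    T = weight_indicator(W1)
    return AttentionProfile(T=T, T_nor=normalize_indicator(T),
                            source="attention_ann")


def sample_wavelengths(profile: AttentionProfile, nw: int, seed) -> np.ndarray:
    """Draw nw distinct wavelength indices from T_nor, without replacement.

    Sequential draws with renormalization after each pick; the result is
    returned sorted ascending so downstream convolutions act along the
    spectral axis in physical order. ``seed`` may be an int or a Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p = np.array(profile.T_nor, dtype=float)
    n_positive = int((p > 0).sum())
    if not 1 <= nw <= n_positive:
        raise ValueError(
            f"nw={nw} outside [1, {n_positive}] positive-probability wavelengths")
    chosen = np.empty(nw, dtype=int)
    for k in range(nw):
        p = p / p.sum()
        idx = rng.choice(p.size, p=p)
        chosen[k] = idx
        p[idx] = 0.0
    return np.sort(chosen)


# ---------------------------------------------------------------------------
# NIPALS PLS1


@dataclass
class PLSModel:
    """PLS1 fit on standardized X and centered y.

    ``regression_coefficients`` are on the standardized-X scale with
    predictions on the original y scale (percent).
    """

    n_components: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    regression_coefficients: np.ndarray


def nipals_pls_fit(trainset: SpectraSet, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS on standardized X, centered y.

    Zero-variance columns get SD 1 during standardization (they are inert
    after centering). ``n_components`` is capped by min(n_samples - 1, m).
    """
    X = np.array(trainset.spectra, dtype=float)
    y = np.array(trainset.targets, dtype=float)
    n, m = X.shape
    rank_bound = min(n - 1, m)
    if not 1 <= n_components <= rank_bound:
        raise ValueError(
            f"n_components={n_components} outside [1, {rank_bound}]")
    std = Standardizer(X)
    Xc = std.transform(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((m, n_components))
    Pl = np.zeros((m, n_components))
    q = np.zeros(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for k in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # residual X carries no covariance with y; stop early
            W, Pl, q = W[:, :k], Pl[:, :k], q[:k]
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        qk = float(yd @ t) / tt
        Xd -= np.outer(t, p)
        yd -= qk * t
        W[:, k], Pl[:, k], q[k] = w, p, qk
    if W.shape[1] == 0:
        raise ValueError("no usable PLS component (X uncorrelated with y)")
    beta = W @ np.linalg.solve(Pl.T @ W, q)
    return PLSModel(n_components=W.shape[1], x_mean=std.mean, x_sd=std.sd,
                    y_mean=y_mean, regression_coefficients=beta)


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict concentrations (percent) for rows of X on the model's grid."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X.shape} but model expects {model.x_mean.size} columns")
    Xs = (X - model.x_mean) / model.x_sd
    return model.y_mean + Xs @ model.regression_coefficients


def regression_coefficient_profile(model: PLSModel) -> AttentionProfile:
    """Importance profile from |PLS regression coefficients| (RC selector)."""
    T = np.abs(model.regression_coefficients)
    return AttentionProfile(T=T, T_nor=normalize_indicator(T),
                            source="pls_coefficient")


def select_pls_components(trainset: SpectraSet, grid=range(3, 26),
                          k_folds: int = 5, seed: int = 0) -> int:
    """Pick the latent-variable count by internal k-fold CV (first-best tie)."""
    n = trainset.n_samples
    rank_bound = min(n - 1, trainset.n_wavelengths)
    candidates = [c for c in grid if 1 <= c <= rank_bound]
    if not candidates:
        raise ValueError("no candidate component count within the rank bound")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    best_c, best_rmse = None, np.inf
    for c in candidates:
        errs = []
        for fold in folds:
            if fold.size == 0:
                continue
            train_idx = np.setdiff1d(order, fold)
            if c > min(train_idx.size - 1, trainset.n_wavelengths):
                errs = None
                break
            model = nipals_pls_fit(trainset.subset(train_idx), c)
            pred = pls_predict(model, trainset.spectra[fold])
            errs.append(np.mean((pred - trainset.targets[fold]) ** 2))
        if errs is None:
            continue
        rmse = float(np.sqrt(np.mean(errs)))
        if rmse < best_rmse - 1e-12:
            best_rmse, best_c = rmse, c
    if best_c is None:
        raise ValueError("component selection failed for all candidates")
    return best_c
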