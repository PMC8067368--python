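"""The 1-D fully-convolutional regression sub-model and its training loop.

Each sub-model sees only a subset of wavelengths (its input is a short 1-D
"spectrum" of nw channels-of-one signal) and is deliberately small:

    [batchnorm -> conv(16 filters, kernel 5, stride 1, same padding)
     -> LeakyReLU] x 3
    -> output layer: sigmoid(affine map of the flattened feature map)

There is no pooling, no stride > 1 and no hidden fully-connected layer: with
so few input variables those operations discard information, and the single
affine output node keeps the parameter count small. The sigmoid output is
mapped back to concentration percent through the training-set target scaler.

Training is full-batch (the calibration sets are tiny) by Adam on the mean
squared error in scaled-target space. Batch statistics drive batch-norm
during training; exponentially-averaged running statistics (momentum 0.9)
are frozen for inference, so a prediction never depends on the other samples
in the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import TargetScaler, fit_target_scaler
from .nnet import (DivergenceError, Standardizer, leaky_relu,
                   make_optimizer, sigmoid)

__all__ = ["CNNConfig", "SubModel", "build_submodel", "train_submodel",
           "predict_submodel"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class CNNConfig:
    """Architecture and training hyper-parameters of one sub-model."""

    n_conv_layers: int = 3
    n_filters: int = 16
    kernel_size: int = 5
    stride: int = 1
    padding: bool = True
    leaky_divisor: float = 10.0
    learning_rate: float = 1e-4
    n_iterations: int = 2000
    optimizer: str = "adam"
    dtype: str = "float32"  # training compute dtype; float64 for gradient checks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        if self.stride != 1:
            raise ValueError("stride must be 1 (pooling/striding is disallowed)")
        if not self.padding:
            raise ValueError("same-length padding is required")
        if self.leaky_divisor <= 1:
            raise ValueError("leaky_divisor must be > 1")
        if self.n_conv_layers < 1 or self.n_filters < 1:
            raise ValueError("need at least one conv layer and one filter")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubModel:
    """One convolutional regressor plus its sampling and scaling state."""

    config: CNNConfig
    wavelength_indices: np.ndarray
    params: dict = field(default_factory=dict)
    bn_running: list = field(default_factory=list)  # [(mean, var), ...]
    sample_indices: np.ndarray | None = None
    x_standardizer: Standardizer | None = None
    target_scaler: TargetScaler | None = None
    loss_trajectory: np.ndarray | None = None

    @property
    def nw(self) -> int:
        return self.wavelength_indices.size

    @property
    def n_parameters(self) -> int:
        return sum(p.size for ps in self.params.values() for p in
                   (ps if isinstance(ps, (list, tuple)) else [ps]))


def build_submodel(nw: int, config: CNNConfig,
                   wavelength_indices=None) -> SubModel:
    """Allocate a sub-model with seeded fan-in-scaled random weights.

    Per conv block: batch-norm scale/shift over the incoming channels, then a
    (n_filters x in_channels x kernel) filter bank with bias. The output layer
    maps the flattened (n_filters x nw) feature map to a single logit.
    """
    K = config.kernel_size
    if nw < K:
        raise ValueError(f"nw={nw} must be >= kernel_size={K}")
    if wavelength_indices is None:
        wavelength_indices = np.arange(nw)
    wavelength_indices = np.asarray(wavelength_indices, dtype=int)
    if wavelength_indices.size != nw:
        raise ValueError("wavelength_indices length must equal nw")
    if np.any(np.diff(wavelength_indices) <= 0):
        raise ValueError("wavelength_indices must be sorted and distinct")

    rng = np.random.default_rng(config.seed)
    F = config.n_filters
    conv_W, conv_b, bn_gamma, bn_beta, bn_running = [], [], [], [], []
    c_in = 1
    for _ in range(config.n_conv_layers):
        bn_gamma.append(np.ones(c_in))
        bn_beta.append(np.zeros(c_in))
        bn_running.append((np.zeros(c_in), np.ones(c_in)))
        conv_W.append(rng.standard_normal((F, c_in, K))
                      * np.sqrt(2.0 / (c_in * K)))
        conv_b.append(np.zeros(F))
        c_in = F
    D = F * nw
    out_w = rng.standard_normal(D) * np.sqrt(1.0 / D)
    out_b = np.zeros(1)
    params = {"conv_W": conv_W, "conv_b": conv_b,
              "bn_gamma": bn_gamma, "bn_beta": bn_beta,
              "out_w": out_w, "out_b": out_b}
    return SubModel(config=config, wavelength_indices=wavelength_indices,
                    params=params, bn_running=bn_running)


def _window_cols(x: np.ndarray, K: int) -> np.ndarray:
    """im2col for channels-last (N, L, C) input with same-length padding.

    In channels-last memory order each length-K window is one contiguous
    slab of K*C floats, so the gather is a cheap row-wise copy. Returns
    (N*L, K*C) with element [n*L + l, k*C + c] = x_padded[n, l + k, c].
    """
    N, L, C = x.shape
    P = (K - 1) // 2
    # np.pad preserves the input's memory order; the stride arithmetic below
    # requires C order, so force it (free when already contiguous)
    xp = np.ascontiguousarray(np.pad(x, ((0, 0), (P, P), (0, 0))))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(N, L, K * C), strides=(s[0], s[1], xp.itemsize))
    return np.ascontiguousarray(view).reshape(N * L, K * C)


def _conv_same(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Cross-correlation with symmetric zero padding, channels-last.

    x is (N, L, C_in); W is (F, C_in, K). Returns ((N, L, F), cols) where
    ``cols`` is the im2col matrix reused by the backward pass.
    """
    F, C, K = W.shape
    N, L, _ = x.shape
    cols = _window_cols(x, K)
    Wt = np.ascontiguousarray(W.transpose(0, 2, 1)).reshape(F, K * C)
    out = cols @ Wt.T + b
    return out.reshape(N, L, F), cols


def _conv_same_backward(dout, cols, W):
    """Gradients of _conv_same: returns (dx, dW, db).

    dx is the transposed convolution of dout with the flipped filters,
    evaluated as a second im2col matmul.
    """
    F, C, K = W.shape
    N, L, _ = dout.shape
    dm = dout.reshape(N * L, F)
    dW = (dm.T @ cols).reshape(F, K, C).transpose(0, 2, 1)
    db = dm.sum(axis=0)
    colsD = _window_cols(dout, K)                      # (N*L, K*F)
    Wrot = np.ascontiguousarray(
        W[:, :, ::-1].transpose(1, 2, 0)).reshape(C, K * F)
    dx = (colsD @ Wrot.T).reshape(N, L, C)
    return dx, dW, db


def _forward(model: SubModel, x: np.ndarray, training: bool):
    """Forward pass on channels-last (N, nw, 1) input; caches if training."""
    p = model.params
    a = model.config.leaky_divisor
    inv_a = 1.0 / a
    cache = []
    h = x
    for l in range(model.config.n_conv_layers):
        gamma, beta = p["bn_gamma"][l], p["bn_beta"][l]
        C = h.shape[2]
        if training:
            h2 = h.reshape(-1, C)
            M = h2.shape[0]
            mean = h2.sum(axis=0) / M
            var = np.maximum((h2 * h2).sum(axis=0) / M - mean * mean, 0.0)
            rm, rv = model.bn_running[l]
            rm *= _BN_MOMENTUM
            rm += (1 - _BN_MOMENTUM) * mean
            rv *= _BN_MOMENTUM
            rv += (1 - _BN_MOMENTUM) * var
        else:
            mean, var = model.bn_running[l]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (h - mean) * inv_std
        bn_out = gamma * xhat + beta
        z, cols = _conv_same(bn_out, p["conv_W"][l], p["conv_b"][l])
        h_next = leaky_relu(z, a)
        if training:
            # LeakyReLU derivative as arithmetic on the sign mask
            gmask = (z > 0) * z.dtype.type(1.0 - inv_a) + z.dtype.type(inv_a)
            cache.append((xhat, inv_std, cols, gmask))
        h = h_next
    N = h.shape[0]
    # flattened feature map: position-major, channel-minor
    flat = h.reshape(N, -1)
    logit = flat @ p["out_w"] + p["out_b"][0]
    pred = sigmoid(logit)
    if training:
        return pred, (cache, flat, h.shape)
    return pred


def train_submodel(model: SubModel, X_sub: np.ndarray, y: np.ndarray,
                   config: CNNConfig | None = None) -> SubModel:
    """Train in place on the sub-model's wavelength columns; returns the model.

    ``X_sub`` is (n, nw), already restricted to ``wavelength_indices``;
    ``y`` is in percent. Standardization and the target scaler are fit here
    on the training rows only and frozen into the model.
    """
    if config is None:
        config = model.config
    X_sub = np.asarray(X_sub, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_sub.shape[1] != model.nw:
        raise ValueError(
            f"X_sub has {X_sub.shape[1]} columns, expected nw={model.nw}")
    model.x_standardizer = Standardizer(X_sub)
    model.target_scaler = fit_target_scaler(y)
    dt = np.dtype(config.dtype)
    x = model.x_standardizer.transform(X_sub)[:, :, None].astype(dt)
    yt = model.target_scaler.scale(y).astype(dt)
    N = x.shape[0]

    p = model.params
    for key in ("conv_W", "conv_b", "bn_gamma", "bn_beta"):
        p[key] = [arr.astype(dt) for arr in p[key]]
    p["out_w"] = p["out_w"].astype(dt)
    p["out_b"] = p["out_b"].astype(dt)
    model.bn_running = [(mu.astype(dt), var.astype(dt))
                        for mu, var in model.bn_running]
    L = config.n_conv_layers
    a = config.leaky_divisor
    flat_params = (p["conv_W"] + p["conv_b"] + p["bn_gamma"] + p["bn_beta"]
                   + [p["out_w"], p["out_b"]])
    opt = make_optimizer(config.optimizer, flat_params, config.learning_rate)
    losses = np.empty(config.n_iterations)

    for it in range(config.n_iterations):
        pred, (cache, flat, hshape) = _forward(model, x, training=True)
        resid = pred - yt
        loss = float(np.mean(resid ** 2))
        losses[it] = loss
        if not np.isfinite(loss):
            raise DivergenceError(f"sub-model training diverged at iteration {it}")

        dlogit = (2.0 / N) * resid * pred * (1.0 - pred)
        d_out_w = flat.T @ dlogit
        d_out_b = np.array([dlogit.sum()])
        dflat = np.outer(dlogit, p["out_w"])
        dh = dflat.reshape(hshape)

        d_conv_W = [None] * L
        d_conv_b = [None] * L
        d_gamma = [None] * L
        d_beta = [None] * L
        for l in reversed(range(L)):
            xhat, inv_std, cols, gmask = cache[l]
            dz = dh * gmask
            dbn_out, d_conv_W[l], d_conv_b[l] = _conv_same_backward(
                dz, cols, p["conv_W"][l])
            gamma = p["bn_gamma"][l]
            C = dbn_out.shape[2]
            d_gamma[l] = (dbn_out * xhat).reshape(-1, C).sum(axis=0)
            d_beta[l] = dbn_out.reshape(-1, C).sum(axis=0)
            dxhat = dbn_out * gamma
            M = dbn_out.shape[0] * dbn_out.shape[1]
            # sums of dxhat and dxhat*xhat reduce to gamma-scaled d_beta/d_gamma
            s1 = gamma * d_beta[l]
            s2 = gamma * d_gamma[l]
            dh = (inv_std / M) * (M * dxhat - s1 - xhat * s2)
        opt.step(d_conv_W + d_conv_b + d_gamma + d_beta + [d_out_w, d_out_b])

    model.loss_trajectory = losses
    return model


def predict_submodel(model: SubModel, X: np.ndarray) -> np.ndarray:
    """Predict concentrations (percent) in inference mode (frozen batch-norm).

    ``X`` may be the full preprocessed wavelength grid (columns are selected
    by ``wavelength_indices``) or already restricted to exactly nw columns.
    """
    if model.x_standardizer is None or model.target_scaler is None:
        raise RuntimeError("sub-model is untrained")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == model.nw:
        X_sub = X
    elif X.shape[1] > int(model.wavelength_indices.max()):
        X_sub = X[:, model.wavelength_indices]
    else:
        raise ValueError(
            f"X has {X.shape[1]} columns; expected nw={model.nw} or a full "
            f"grid covering index {int(model.wavelength_indices.max())}")
    x = model.x_standardizer.transform(X_sub)[:, :, None]
    pred = _forward(model, x, training=False)
    return model.target_scaler.unscale(pred)


def forward_scaled(model: SubModel, X_sub: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass in scaled (0,1) space, without the
    standardizer/target-scaler bookkeeping. Used by oracle cross-checks."""
    x = np.atleast_2d(np.asarray(X_sub, dtype=float))[:, :, None]
    return _forward(model, x, training=False)
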