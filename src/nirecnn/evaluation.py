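"""Nested cross-validation protocol, prediction metrics, and the
attention-vs-random sub-model comparison experiment.

Final accuracy is reported by external k-fold cross-validation: per fold, a
method is fit on k-1 partitions (all statistics — standardization, target
scaling, importance profiles — computed inside the training partitions only)
and scored on the held-out partition by RMSEP, the determination coefficient
R² = 1 - SS_res/SS_tot (prediction R², can be negative), and RPD = SD/RMSEP
with SD the population standard deviation of the fold's true targets.
Hyper-parameters are chosen by a separate internal cross-validation within
each training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .attention import nipals_pls_fit, pls_predict, sample_wavelengths, \
    select_pls_components
from .cnn import CNNConfig, build_submodel, predict_submodel, train_submodel
from .dataset import SpectraSet
from .ensemble import EnsembleConfig, fit_ensemble, predict_ensemble

__all__ = ["rmsep", "r_squared", "rpd", "EvaluationReport", "external_cv",
           "internal_cv_optimize", "selection_comparison",
           "ensemble_method", "cnn_method", "pls_method"]

# A method is fit_predict(trainset, X_test, seed) -> predicted percent.
# Test targets are never passed in, so leakage is excluded structurally.
Method = Callable[[SpectraSet, np.ndarray, int], np.ndarray]


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length 1-D, n >= 2")
    return y_true, y_pred


def rmsep(y_true, y_pred) -> float:
    """Root mean squared error of prediction, in percent."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """1 - SS_res/SS_tot on the test set (can be negative)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant y_true: R² undefined")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rpd(y_true, y_pred) -> float:
    """SD(y_true)/RMSEP with population SD; +inf for perfect predictions."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    sd = float(np.std(y_true))
    if sd == 0:
        raise ValueError("constant y_true: RPD undefined")
    err = rmsep(y_true, y_pred)
    return float("inf") if err == 0 else sd / err


@dataclass
class EvaluationReport:
    per_fold: pd.DataFrame            # fold, rmsep, r2, rpd
    aggregate: dict                   # metric -> (mean, sd)
    fold_assignments: list[np.ndarray]
    seed: int
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.per_fold.copy()


def _make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def external_cv(data: SpectraSet, method: Method, k_external: int = 10,
                seed: int = 0, config: dict | None = None) -> EvaluationReport:
    """External k-fold cross-validation of any fit/predict method.

    Samples are shuffled (seeded) and partitioned into k folds; each fold in
    turn is the independent test set while the method is fit on the rest.
    Per-fold RMSEP/R²/RPD are aggregated as mean ± SD. Folds with constant
    targets are flagged and excluded from the RPD/R² aggregates.
    """
    n = data.n_samples
    if n < 2 * k_external:
        raise ValueError(f"need at least {2 * k_external} samples for "
                         f"{k_external}-fold CV")
    folds = _make_folds(n, k_external, seed)
    rows = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        fold_seed = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(f,)).generate_state(1)[0] % (2**31))
        pred = np.asarray(method(data.subset(train_idx),
                                 data.spectra[test_idx], fold_seed))
        y_true = data.targets[test_idx]
        row = {"fold": f, "rmsep": rmsep(y_true, pred)}
        if np.ptp(y_true) == 0:
            row.update({"r2": np.nan, "rpd": np.nan, "flag": "constant_targets"})
        else:
            row.update({"r2": r_squared(y_true, pred),
                        "rpd": rpd(y_true, pred), "flag": ""})
        rows.append(row)
    per_fold = pd.DataFrame(rows)
    aggregate = {}
    for metric in ("rmsep", "r2", "rpd"):
        vals = per_fold[metric].dropna().to_numpy()
        aggregate[metric] = (float(np.mean(vals)), float(np.std(vals)))
    return EvaluationReport(per_fold=per_fold, aggregate=aggregate,
                            fold_assignments=folds, seed=seed,
                            config=config or {})


def internal_cv_optimize(trainset: SpectraSet, param_grid: list,
                         method_factory: Callable[[object], Method],
                         k_internal: int = 5, seed: int = 0):
    """Grid point minimizing mean internal-fold RMSEP; first-in-grid ties win."""
    if not param_grid:
        raise ValueError("empty parameter grid")
    n = trainset.n_samples
    folds = _make_folds(n, k_internal, seed)
    best_params, best_score = None, np.inf
    for params in param_grid:
        method = method_factory(params)
        scores = []
        for f, val_idx in enumerate(folds):
            tr_idx = np.setdiff1d(np.arange(n), val_idx)
            fold_seed = int(np.random.SeedSequence(
                entropy=seed, spawn_key=(f,)).generate_state(1)[0] % (2**31))
            pred = method(trainset.subset(tr_idx),
                          trainset.spectra[val_idx], fold_seed)
            scores.append(rmsep(trainset.targets[val_idx], pred))
        score = float(np.mean(scores))
        if score < best_score - 1e-12:
            best_score, best_params = score, params
    return best_params


def selection_comparison(data: SpectraSet, n_submodels: int = 500,
                         nw: int = 25, seed: int = 0, k_folds: int = 10,
                         submodel_config: CNNConfig | None = None,
                         attention_config=None) -> pd.DataFrame:
    """Attention vs uniform-random wavelength selection at the sub-model level.

    Within each of k external folds, ``n_submodels // k_folds`` sub-models per
    selector are trained on *all* training samples (rs = 1 for this
    experiment) with nw wavelengths drawn from the attention profile or
    uniformly, then scored on the fold's test set. Returns one row per
    sub-model with columns selector/fold/rmse, for histogram plotting.
    """
    from .attention import train_attention_ann, uniform_profile, AttentionConfig

    if submodel_config is None:
        submodel_config = CNNConfig()
    if attention_config is None:
        attention_config = AttentionConfig()
    per_fold = max(1, n_submodels // k_folds)
    n = data.n_samples
    folds = _make_folds(n, k_folds, seed)
    rows = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        trainset = data.subset(train_idx)
        X_test, y_test = data.spectra[test_idx], data.targets[test_idx]
        fold_ss = np.random.SeedSequence(entropy=seed, spawn_key=(f,))
        acfg = AttentionConfig(**{**attention_config.__dict__,
                                  "seed": int(fold_ss.generate_state(1)[0] % (2**31))})
        profiles = {"attention": train_attention_ann(trainset, acfg),
                    "random": uniform_profile(trainset.n_wavelengths)}
        for sel, profile in profiles.items():
            for j in range(per_fold):
                ss = np.random.SeedSequence(
                    entropy=seed, spawn_key=(f, 0 if sel == "attention" else 1, j))
                rng = np.random.default_rng(ss)
                wl_idx = sample_wavelengths(profile, nw, rng)
                cfg = CNNConfig(**{**submodel_config.to_dict(),
                                   "seed": int(ss.generate_state(1)[0] % (2**31))})
                sub = build_submodel(nw, cfg, wavelength_indices=wl_idx)
                train_submodel(sub, trainset.spectra[:, wl_idx],
                               trainset.targets)
                pred = predict_submodel(sub, X_test)
                rows.append({"selector": sel, "fold": f, "submodel": j,
                             "rmse": rmsep(y_test, pred)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Method adapters for external_cv


def ensemble_method(config: EnsembleConfig) -> Method:
    """AM/RC/random-selector ensemble as an external_cv method."""

    def fit_predict(trainset: SpectraSet, X_test: np.ndarray,
                    seed: int) -> np.ndarray:
        cfg = EnsembleConfig(**{**_ensemble_kwargs(config), "seed": seed})
        model = fit_ensemble(trainset, cfg)
        return predict_ensemble(model, X_test)

    return fit_predict


def _ensemble_kwargs(config: EnsembleConfig) -> dict:
    return dict(n_submodels=config.n_submodels, nw=config.nw, rs=config.rs,
                selector=config.selector,
                submodel_config=config.submodel_config,
                attention_config=config.attention_config,
                pls_components=config.pls_components, seed=config.seed)


def cnn_method(config: CNNConfig | None = None) -> Method:
    """Single full-spectrum convolutional regressor as an external_cv method."""
    base = config or CNNConfig()

    def fit_predict(trainset: SpectraSet, X_test: np.ndarray,
                    seed: int) -> np.ndarray:
        m = trainset.n_wavelengths
        cfg = CNNConfig(**{**base.to_dict(), "seed": seed})
        sub = build_submodel(m, cfg, wavelength_indices=np.arange(m))
        train_submodel(sub, trainset.spectra, trainset.targets)
        return predict_submodel(sub, X_test)

    return fit_predict


def pls_method(n_components: int | None = None,
               component_grid=range(3, 26)) -> Method:
    """PLS baseline; latent variables picked by internal 5-fold CV if None."""

    def fit_predict(trainset: SpectraSet, X_test: np.ndarray,
                    seed: int) -> np.ndarray:
        n_comp = n_components
        if n_comp is None:
            n_comp = select_pls_components(trainset, grid=component_grid,
                                           seed=seed)
        model = nipals_pls_fit(trainset, n_comp)
        return pls_predict(model, X_test)

    return fit_predict
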