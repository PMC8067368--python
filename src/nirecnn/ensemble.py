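"""Ensemble construction, simple-average prediction, and the
accuracy/diversity diagnostics used to tune it.

The ensemble is built in six steps: (1) split off a training set; (2) train
the selector (attention network or PLS) on all training samples and all
wavelengths; (3) normalize its importance profile into a sampling
distribution; (4) for each sub-model, draw nw wavelengths from that
distribution and a uniform-random rs-fraction of the training samples, the
rest becoming that sub-model's validation samples; (5) train the sub-models;
(6) average their predictions.

Two diagnostics drive the choice of (rs, nw): RMSEV, the pooled RMSE of each
sub-model on its own held-out validation samples (accuracy), and MSDV, the
mean over samples of the standard deviation of the sub-model predictions on
that sample (diversity). A good operating point keeps RMSEV near its plateau
while retaining nonzero MSDV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attention import (AttentionConfig, AttentionProfile, nipals_pls_fit,
                        regression_coefficient_profile, sample_wavelengths,
                        select_pls_components, train_attention_ann,
                        uniform_profile)
from .cnn import CNNConfig, SubModel, build_submodel, predict_submodel, \
    train_submodel
from .dataset import SpectraSet

__all__ = ["EnsembleConfig", "EnsembleModel", "fit_ensemble",
           "predict_ensemble", "rmsev", "msdv", "grid_search"]

SELECTORS = ("attention_ann", "pls_coefficient", "uniform_random")


@dataclass
class EnsembleConfig:
    """Hyper-parameters of the ensemble.

    nw is the number of wavelengths per sub-model, rs the fraction of
    training samples each sub-model is fit on (its complement is that
    sub-model's validation set).
    """

    n_submodels: int = 50
    nw: int = 30
    rs: float = 0.60
    selector: str = "attention_ann"
    submodel_config: CNNConfig = field(default_factory=CNNConfig)
    attention_config: AttentionConfig = field(default_factory=AttentionConfig)
    pls_components: int | None = None  # None: pick by internal 5-fold CV
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rs < 1.0:
            raise ValueError(f"rs must be in (0, 1), got {self.rs}")
        if self.n_submodels < 2:
            raise ValueError("n_submodels must be >= 2")
        if self.nw < self.submodel_config.kernel_size:
            raise ValueError(
                f"nw={self.nw} must be >= kernel_size="
                f"{self.submodel_config.kernel_size}")
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")


@dataclass
class EnsembleModel:
    submodels: list[SubModel]
    profile: AttentionProfile
    config: EnsembleConfig
    validation_assignments: list[np.ndarray]  # per sub-model, train-set rows


def _submodel_seed(seed: int, index: int) -> np.random.SeedSequence:
    # spawn_key derivation: adding sub-models never perturbs earlier draws
    return np.random.SeedSequence(entropy=seed, spawn_key=(index,))


def build_selector_profile(trainset: SpectraSet,
                           config: EnsembleConfig) -> AttentionProfile:
    """Train the wavelength-importance profile on the full training set."""
    if config.selector == "uniform_random":
        return uniform_profile(trainset.n_wavelengths)
    selector_seed = int(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0x5E1EC7,)).generate_state(1)[0] % (2**31))
    if config.selector == "attention_ann":
        acfg = AttentionConfig(**{**config.attention_config.__dict__,
                                  "seed": selector_seed})
        return train_attention_ann(trainset, acfg)
    n_comp = config.pls_components
    if n_comp is None:
        n_comp = select_pls_components(trainset, seed=selector_seed)
    return regression_coefficient_profile(nipals_pls_fit(trainset, n_comp))


def fit_ensemble(trainset: SpectraSet, config: EnsembleConfig) -> EnsembleModel:
    """Fit the full ensemble on a preprocessed training set.

    Fully seeded: ``config.seed`` plus the sub-model index determine every
    wavelength draw, sample draw and weight initialization.
    """
    profile = build_selector_profile(trainset, config)
    n = trainset.n_samples
    n_tr = max(2, int(np.floor(config.rs * n)))
    if n_tr >= n:
        raise ValueError("rs leaves no validation samples")

    submodels: list[SubModel] = []
    validation: list[np.ndarray] = []
    for i in range(config.n_submodels):
        ss = _submodel_seed(config.seed, i)
        rng = np.random.default_rng(ss)
        try:
            wl_idx = sample_wavelengths(profile, config.nw, rng)
            perm = rng.permutation(n)
            train_rows = np.sort(perm[:n_tr])
            valid_rows = np.sort(perm[n_tr:])
            sub_cfg = CNNConfig(**{**config.submodel_config.to_dict(),
                                   "seed": int(ss.generate_state(1)[0] % (2**31))})
            sub = build_submodel(config.nw, sub_cfg, wavelength_indices=wl_idx)
            train_submodel(sub, trainset.spectra[np.ix_(train_rows, wl_idx)],
                           trainset.targets[train_rows])
            sub.sample_indices = train_rows
        except Exception as exc:
            raise RuntimeError(f"sub-model {i} failed: {exc}") from exc
        submodels.append(sub)
        validation.append(valid_rows)
    return EnsembleModel(submodels=submodels, profile=profile, config=config,
                         validation_assignments=validation)


def predict_ensemble(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Simple average of the sub-model predictions, in percent."""
    if not model.submodels:
        raise ValueError("ensemble has no sub-models")
    preds = np.stack([predict_submodel(s, X) for s in model.submodels])
    return preds.mean(axis=0)


def _validation_predictions(model: EnsembleModel, trainset: SpectraSet):
    """(n_submodels, n_train) prediction matrix + boolean validation mask."""
    n = trainset.n_samples
    preds = np.stack([predict_submodel(s, trainset.spectra)
                      for s in model.submodels])
    mask = np.zeros((len(model.submodels), n), dtype=bool)
    for j, rows in enumerate(model.validation_assignments):
        mask[j, rows] = True
    return preds, mask


def rmsev(model: EnsembleModel, trainset: SpectraSet) -> float:
    """Pooled validation RMSE over all (sub-model, held-out sample) pairs."""
    preds, mask = _validation_predictions(model, trainset)
    if not mask.any():
        raise ValueError("no validation pairs recorded")
    err = preds - trainset.targets[None, :]
    return float(np.sqrt(np.mean(err[mask] ** 2)))


def msdv(model: EnsembleModel, trainset: SpectraSet) -> float:
    """Mean over samples of the population SD of validation predictions.

    Only samples held out by at least two sub-models contribute (a single
    prediction has no spread).
    """
    preds, mask = _validation_predictions(model, trainset)
    counts = mask.sum(axis=0)
    usable = counts >= 2
    if not usable.any():
        raise ValueError("no sample is validated by >= 2 sub-models")
    sds = []
    for i in np.flatnonzero(usable):
        vals = preds[mask[:, i], i]
        sds.append(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
    return float(np.mean(sds))


def grid_search(trainset: SpectraSet, rs_grid, nw_grid,
                base_config: EnsembleConfig) -> pd.DataFrame:
    """RMSEV/MSDV table over the (rs, nw) cross product.

    One ensemble is fit per grid point with a seed derived from the base seed
    and the grid position; selection of the operating point is left to the
    caller (typically where both curves plateau).
    """
    rs_grid = list(rs_grid)
    nw_grid = list(nw_grid)
    if not rs_grid or not nw_grid:
        raise ValueError("rs_grid and nw_grid must be non-empty")
    rows = []
    for ri, rs in enumerate(rs_grid):
        for ni, nw in enumerate(nw_grid):
            seed = int(np.random.SeedSequence(
                entropy=base_config.seed,
                spawn_key=(ri, ni)).generate_state(1)[0] % (2**31))
            cfg = EnsembleConfig(
                n_submodels=base_config.n_submodels, nw=nw, rs=rs,
                selector=base_config.selector,
                submodel_config=base_config.submodel_config,
                attention_config=base_config.attention_config,
                pls_components=base_config.pls_components, seed=seed)
            model = fit_ensemble(trainset, cfg)
            rows.append({"rs": rs, "nw": nw,
                         "rmsev": rmsev(model, trainset),
                         "msdv": msdv(model, trainset)})
    return pd.DataFrame(rows)
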