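"""Core spectra container, CSV I/O and the preprocessing chain.

The exchange object throughout the package is :class:`SpectraSet`: a matrix of
NIR spectra on a common wavelength grid plus a per-sample adulterant
concentration (in mass-fraction percent). Preprocessing follows standard
chemometrics practice for reflectance-derived NIR data: trim the noisy grid
ends, then take a Savitzky–Golay first derivative for baseline correction and
smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectraSet",
    "TargetScaler",
    "read_spectra_csv",
    "write_spectra_csv",
    "trim_wavelengths",
    "sg_first_derivative",
    "fit_target_scaler",
]


class SpectraFormatError(ValueError):
    """Raised when a spectra table violates the expected layout."""


@dataclass
class SpectraSet:
    """NIR spectra on a shared wavelength grid with concentration targets.

    Parameters
    ----------
    wavelengths : array, shape (m,)
        Strictly increasing wavelength grid in nm.
    spectra : array, shape (n_samples, m)
        Absorbance/reflectance-derived intensities (arbitrary units).
    targets : array, shape (n_samples,)
        Adulterant concentration in mass-fraction percent.
    sample_ids : list of str
        One label per sample row.
    """

    wavelengths: np.ndarray
    spectra: np.ndarray
    targets: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float)
        n, m = self.spectra.shape
        if self.wavelengths.ndim != 1 or self.wavelengths.size != m:
            raise SpectraFormatError(
                f"spectra have {m} columns but {self.wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraFormatError("wavelengths not strictly increasing")
        if self.targets.shape != (n,):
            raise SpectraFormatError(
                f"targets length {self.targets.size} != {n} samples"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise SpectraFormatError("sample_ids length mismatch")
        for name, arr in (("wavelengths", self.wavelengths),
                          ("spectra", self.spectra),
                          ("targets", self.targets)):
            if not np.all(np.isfinite(arr)):
                raise SpectraFormatError(f"non-finite values in {name}")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.spectra.shape[1]

    def subset(self, indices) -> "SpectraSet":
        """Row subset (samples), preserving order of *indices*."""
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            spectra=self.spectra[indices],
            targets=self.targets[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
        )


def read_spectra_csv(path) -> SpectraSet:
    """Read a SpectraSet from CSV with header ``id,<wl1>,...,<wlm>,target``."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "id" or cols[-1] != "target":
        raise SpectraFormatError(
            "expected header 'id,<wl1>,...,target', got "
            f"{cols[:2]}...{cols[-1:]}"
        )
    try:
        wavelengths = np.array([float(c) for c in cols[1:-1]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from None
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectraFormatError("wavelengths not strictly increasing")
    if df.isna().any().any():
        raise SpectraFormatError("missing values (ragged rows?) in spectra CSV")
    return SpectraSet(
        wavelengths=wavelengths,
        spectra=df.iloc[:, 1:-1].to_numpy(dtype=float),
        targets=df["target"].to_numpy(dtype=float),
        sample_ids=[str(v) for v in df["id"]],
    )


def write_spectra_csv(sset: SpectraSet, path) -> None:
    """Write a SpectraSet to CSV (UTF-8, '.' decimal), round-trip safe."""
    df = pd.DataFrame(sset.spectra,
                      columns=[repr(float(w)) for w in sset.wavelengths])
    df.insert(0, "id", sset.sample_ids)
    df["target"] = sset.targets
    # repr() keeps 17 significant digits so write->read is value-exact
    df.to_csv(path, index=False, float_format="%.17g")


def trim_wavelengths(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep only columns with lo <= wavelength <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError(f"trim bounds must satisfy lo < hi, got {lo} >= {hi}")
    mask = (sset.wavelengths >= lo) & (sset.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no wavelengths in [{lo}, {hi}]")
    return SpectraSet(
        wavelengths=sset.wavelengths[mask],
        spectra=sset.spectra[:, mask],
        targets=sset.targets.copy(),
        sample_ids=list(sset.sample_ids),
    )


def sg_first_derivative(sset: SpectraSet, window: int = 9,
                        polyorder: int = 2) -> SpectraSet:
    """Savitzky–Golay first derivative of each spectrum, in a.u. per nm.

    Edge points are handled by fitting the local polynomial on the one-sided
    window (``mode='interp'``) so the output keeps the full wavelength grid.
    The derivative is scaled by the grid step, i.e. expressed per nm.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and > polyorder, got window={window}, "
            f"polyorder={polyorder}"
        )
    if sset.n_wavelengths < window:
        raise ValueError(f"need at least {window} wavelengths")
    steps = np.diff(sset.wavelengths)
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-6):
        raise ValueError("wavelength grid must be uniform for SG derivative")
    deriv = savgol_filter(sset.spectra, window_length=window,
                          polyorder=polyorder, deriv=1, delta=step,
                          axis=1, mode="interp")
    return SpectraSet(
        wavelengths=sset.wavelengths.copy(),
        spectra=deriv,
        targets=sset.targets.copy(),
        sample_ids=list(sset.sample_ids),
    )


def standard_preprocess(sset: SpectraSet, trim_lo: float = 1000.0,
                        trim_hi: float = 1600.0, window: int = 9,
                        polyorder: int = 2) -> SpectraSet:
    """Trim the noisy grid ends, then SG first derivative (the default chain)."""
    return sg_first_derivative(trim_wavelengths(sset, trim_lo, trim_hi),
                               window=window, polyorder=polyorder)


@dataclass(frozen=True)
class TargetScaler:
    """Affine map between concentration percent and the sigmoid output range.

    The regression networks end in a sigmoid, so targets are mapped into an
    interior interval of (0, 1) — [0.1, 0.9] by default, keeping training
    targets away from sigmoid saturation. ``unscale`` inverts exactly and
    never clamps, so extrapolation beyond the training range round-trips.
    """

    y_min: float
    y_max: float
    out_lo: float = 0.1
    out_hi: float = 0.9

    def __post_init__(self) -> None:
        if self.y_max <= self.y_min:
            raise ValueError(
                f"degenerate target range: y_min={self.y_min} >= y_max={self.y_max}"
            )
        if not (0.0 < self.out_lo < self.out_hi < 1.0):
            raise ValueError("need 0 < out_lo < out_hi < 1")

    def scale(self, y):
        y = np.asarray(y, dtype=float)
        return self.out_lo + (y - self.y_min) / (self.y_max - self.y_min) \
            * (self.out_hi - self.out_lo)

    def unscale(self, p):
        p = np.asarray(p, dtype=float)
        return self.y_min + (p - self.out_lo) / (self.out_hi - self.out_lo) \
            * (self.y_max - self.y_min)


def fit_target_scaler(targets, out_lo: float = 0.1,
                      out_hi: float = 0.9) -> TargetScaler:
    """Fit the scaler on (training) targets only."""
    targets = np.asarray(targets, dtype=float)
    return TargetScaler(float(targets.min()), float(targets.max()),
                        out_lo, out_hi)
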