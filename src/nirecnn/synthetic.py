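"""Seeded synthetic NIR adulteration data sets.

Real milk-powder adulteration spectra for this problem were never deposited,
so the package ships a generator that emulates the statistical structure the
method assumes: a handful of powder "brands" (latent nuisance endmembers built
from broad Gaussian overtone bands), random brand mixtures, a linear mixing
law with the adulterant endmember, plus baseline drift and measurement noise.

Two presets mirror the two study designs:

* ``hlp_like_default`` — a hydrolyzed-leather-protein-like adulterant with
  broad bands overlapping the milk background, mass fraction uniform on
  0–20 %.
* ``melamine_like_default`` — a melamine-like adulterant with a few sharp,
  distinct bands, mass fraction uniform on 0–10 %.

Both live on the 900–1700 nm grid at 2.8 nm steps with 100 samples and three
brands. Peak catalogs are stylized (positions loosely follow the overtone
regions flagged as informative in NIR studies of these adulterants), not
spectroscopically accurate endmembers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import SpectraSet

__all__ = [
    "SyntheticConfig",
    "generate",
    "hlp_like_default",
    "melamine_like_default",
    "sparse_informative_default",
]

Peak = tuple[float, float, float]  # (center nm, width nm, height a.u.)

# Broad milk-powder background bands (water/fat/protein overtone regions).
MILK_PEAKS: list[Peak] = [
    (980.0, 70.0, 0.45),
    (1100.0, 120.0, 0.30),
    (1190.0, 80.0, 0.85),
    (1450.0, 60.0, 1.00),
    (1650.0, 70.0, 0.60),
]

# HLP-like adulterant: broad protein-mixture bands overlapping the milk background.
HLP_PEAKS: list[Peak] = [
    (1160.0, 45.0, 0.90),
    (1285.0, 55.0, 0.80),
    (1500.0, 70.0, 1.00),
]

# Melamine-like adulterant: few sharp, well-separated bands.
MELAMINE_PEAKS: list[Peak] = [
    (1040.0, 14.0, 1.00),
    (1306.0, 12.0, 0.90),
    (1460.0, 16.0, 1.10),
]


@dataclass
class SyntheticConfig:
    """Design of one synthetic adulteration data set.

    ``adulterant_max`` is the upper bound of the uniform mass-fraction
    distribution, in percent. ``brand_jitter`` perturbs each brand's peak
    heights multiplicatively (relative scale). ``drift_scale`` is the SD of
    the random linear+quadratic baseline coefficients; ``noise_sd`` the SD of
    iid measurement noise, both in absorbance units.
    """

    n_samples: int = 100
    wl_start: float = 900.0
    wl_end: float = 1700.0
    wl_step: float = 2.8
    n_brands: int = 3
    adulterant_max: float = 20.0
    base_peaks: list[Peak] = field(default_factory=lambda: list(MILK_PEAKS))
    adulterant_peaks: list[Peak] = field(default_factory=lambda: list(HLP_PEAKS))
    brand_jitter: float = 0.20
    drift_scale: float = 0.01
    noise_sd: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_start >= self.wl_end:
            raise ValueError("wl_start must be < wl_end")
        if self.wl_step <= 0:
            raise ValueError("wl_step must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_brands < 1:
            raise ValueError("n_brands must be >= 1")
        if self.adulterant_max <= 0:
            raise ValueError("adulterant_max must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.drift_scale < 0:
            raise ValueError("drift_scale must be >= 0")
        if self.brand_jitter < 0:
            raise ValueError("brand_jitter must be >= 0")
        for peaks, name in ((self.base_peaks, "base_peaks"),
                            (self.adulterant_peaks, "adulterant_peaks")):
            if not peaks:
                raise ValueError(f"{name} must be non-empty")
            for _, width, _ in peaks:
                if width <= 0:
                    raise ValueError(f"{name}: all peak widths must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def wavelength_grid(config: SyntheticConfig) -> np.ndarray:
    """Grid wl_start + k*wl_step for k = 0,1,... while value <= wl_end."""
    k = int(np.floor((config.wl_end - config.wl_start) / config.wl_step + 1e-9))
    return config.wl_start + np.arange(k + 1) * config.wl_step


def _gaussians(wl: np.ndarray, peaks: list[Peak],
               height_factors=None) -> np.ndarray:
    out = np.zeros_like(wl)
    for p, (center, width, height) in enumerate(peaks):
        h = height if height_factors is None else height * height_factors[p]
        out += h * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def generate(config: SyntheticConfig) -> SpectraSet:
    """Generate a seeded synthetic adulteration SpectraSet.

    Each sample mixes a random brand blend with an adulterant fraction
    c ~ Uniform(0, adulterant_max)/100 under a linear mixing law:

        spectrum = (1 - c) * brand_mix + c * adulterant
                   + baseline(drift) + noise

    Brand endmembers are drawn once per data set (brand identity is a latent
    nuisance factor, not a per-sample effect). Targets are stored in percent.
    The same config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    wl = wavelength_grid(config)
    m = wl.size
    n = config.n_samples

    # one endmember per brand, peak heights jittered once for the whole set
    brand_endmembers = np.empty((config.n_brands, m))
    for b in range(config.n_brands):
        factors = 1.0 + config.brand_jitter * rng.standard_normal(
            len(config.base_peaks))
        factors = np.clip(factors, 0.05, None)
        brand_endmembers[b] = _gaussians(wl, config.base_peaks, factors)
    adulterant = _gaussians(wl, config.adulterant_peaks)

    conc = rng.uniform(0.0, config.adulterant_max, size=n) / 100.0
    brand_weights = rng.dirichlet(np.ones(config.n_brands), size=n)
    t = np.linspace(0.0, 1.0, m)
    drift_coef = config.drift_scale * rng.standard_normal((n, 3))
    noise = config.noise_sd * rng.standard_normal((n, m))

    brand_mix = brand_weights @ brand_endmembers
    baseline = (drift_coef[:, [0]]
                + drift_coef[:, [1]] * t
                + drift_coef[:, [2]] * t ** 2)
    spectra = ((1.0 - conc)[:, None] * brand_mix
               + conc[:, None] * adulterant
               + baseline + noise)
    return SpectraSet(wavelengths=wl, spectra=spectra,
                      targets=conc * 100.0,
                      sample_ids=[f"syn{i:03d}" for i in range(n)])


def hlp_like_default(seed: int = 0) -> SyntheticConfig:
    """Broad-band adulterant design: mass fraction uniform on 0–20 %."""
    return SyntheticConfig(adulterant_max=20.0,
                           adulterant_peaks=list(HLP_PEAKS), seed=seed)


def melamine_like_default(seed: int = 0) -> SyntheticConfig:
    """Sharp-band adulterant design: mass fraction uniform on 0–10 %."""
    return SyntheticConfig(adulterant_max=10.0,
                           adulterant_peaks=list(MELAMINE_PEAKS), seed=seed)


def sparse_informative_default(seed: int = 0) -> SyntheticConfig:
    """Design where only a few narrow bands carry the adulterant signal.

    The background is a single quasi-flat very broad band, so after the
    derivative the non-adulterant channels contain only drift and noise; the
    adulterant contributes two narrow bands and the noise floor is raised so
    their weak flanks carry no usable signal (roughly 10-20 of ~215 channels
    remain informative). This isolates the regime the probabilistic
    wavelength selector targets: sparse informative bands in a mostly
    uninformative grid, where uniform-random subsets often miss the signal.
    """
    return SyntheticConfig(
        adulterant_max=10.0,
        base_peaks=[(1300.0, 600.0, 1.0)],
        adulterant_peaks=[(1110.0, 6.0, 0.8), (1340.0, 7.0, 1.0)],
        n_brands=1,
        brand_jitter=0.0,
        noise_sd=0.02,
        seed=seed,
    )
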