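import numpy as np
import pytest

from nirecnn import (CNNConfig, SpectraSet, generate, melamine_like_default,
                     sparse_informative_default, standard_preprocess)


@pytest.fixture(scope="session")
def melamine_prep():
    """Preprocessed melamine-like preset (trim + SG derivative)."""
    return standard_preprocess(generate(melamine_like_default(seed=11)))


@pytest.fixture(scope="session")
def sparse_prep():
    """Preprocessed sparse-informative set (few informative bands)."""
    return standard_preprocess(generate(sparse_informative_default(seed=11)))


@pytest.fixture
def tiny_spectra():
    """Hand-sized SpectraSet for I/O and preprocessing unit tests."""
    rng = np.random.default_rng(0)
    wl = np.array([900.0, 1000.0, 1300.0, 1600.0, 1700.0])
    return SpectraSet(wavelengths=wl,
                      spectra=rng.normal(size=(4, 5)),
                      targets=np.array([0.0, 5.0, 10.0, 20.0]),
                      sample_ids=["a", "b", "c", "d"])


@pytest.fixture
def fast_cnn_config():
    """Small/short CNN settings for functional tests."""
    return CNNConfig(n_conv_layers=2, n_filters=4, n_iterations=60, seed=0)
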