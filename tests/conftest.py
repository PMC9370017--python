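from dataclasses import replace

import numpy as np
import pytest

from nades_hydrospec import SampleDesign, SplitProtocol, generate_dataset
from nades_hydrospec.synthetic_lalp import default_profiles


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def atr_dataset(profiles):
    """Default ATR-IR dataset (405 spectra), fixed seed."""
    return generate_dataset(SampleDesign(), profiles["ATR-IR"], seed=42)


@pytest.fixture(scope="session")
def noiseless_design():
    """Design with every randomness source switched off."""
    return SampleDesign(intrinsic_water_sd=0.0, weighing_error_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_atr_profile(profiles):
    return replace(
        profiles["ATR-IR"], additive_noise_sd=0.0, deposit_gain_sd=0.0, baseline_scale=0.0
    )


@pytest.fixture(scope="session")
def noiseless_atr_dataset(noiseless_design, noiseless_atr_profile):
    return generate_dataset(noiseless_design, noiseless_atr_profile, seed=7)


@pytest.fixture
def fast_protocol():
    """Reduced iteration count for unit tests; same structure as the default."""
    return SplitProtocol(seed=3, n_iterations=10, max_lv=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
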