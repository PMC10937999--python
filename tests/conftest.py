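import numpy as np
import pytest

from ftir_radsig.synth import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Small-geometry cohort config for fast map-level tests."""
    return SyntheticConfig(
        n_mice_per_group=2, map_shape=(8, 8), n_points=1024, seed=7
    )


@pytest.fixture
def clean_config():
    """Noise-free, artifact-free config: spectra equal the analytic band sum."""
    return SyntheticConfig(
        n_mice_per_group=2, map_shape=(8, 8), n_points=2048,
        noise_sd=0.0, het_noise_coef=0.0, baseline_params={},
        dead_pixel_rate=0.0, co2_amplitude=0.0, animal_effect_sd=0.0,
        pixel_scale_sd=0.0, baseline_pixel_sd=0.0, seed=7,
    )
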