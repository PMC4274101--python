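import numpy as np
import pytest

from cuffmap.synthetic import StackConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Small stack with every degradation disabled and a flat surface."""
    return StackConfig(
        length_um=600, width_um=120,
        upstream_peak_amp=0.0, downstream_peak_amp=0.0,
        bias_amplitude=0.0, attenuation_coeff=0.0, noise=0.0,
        calibration_noise=0.0, glare_amp_fraction=0.0,
        surface_sag=0.0, surface_tilt=0.0,
    )


@pytest.fixture
def curved_clean_config():
    """As clean_config but with the curved luminal surface enabled."""
    return StackConfig(
        length_um=600, width_um=120,
        bias_amplitude=0.0, attenuation_coeff=0.0, noise=0.0,
        calibration_noise=0.0, glare_amp_fraction=0.0,
    )


@pytest.fixture
def noisy_config():
    """Small stack under the default degradations."""
    return StackConfig(length_um=600, width_um=120)


@pytest.fixture
def small_pipeline_stack():
    """StackConfig overrides for end-to-end pipeline runs at reduced size but
    full cuff-frame coverage."""
    return {"length_um": 4800, "width_um": 150, "x_offset": -3400}
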