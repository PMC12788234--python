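import numpy as np
import pytest

from semgintent.config import IFIAConfig, ModelConfig, WindowingConfig
from semgintent.synthetic import QUICK_CLASSES, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model_config():
    """Scaled-down architecture for fast structural/gradient tests; the
    shape ladder logic is identical to the full configuration."""
    return ModelConfig(
        n_channels=3, n_scales=5, window_samples=320, spectrum_bins=41,
        n_classes=4, agg_out_channels=4, tcn_dilations=(1, 2),
        tcn_channels=(6, 8), dropout_p=0.0,
    )


@pytest.fixture(scope="session")
def tiny_ifia_config():
    return IFIAConfig(r=4, n_heads=2, d_model=8)


@pytest.fixture(scope="session")
def default_wcfg():
    return WindowingConfig()


@pytest.fixture(scope="session")
def small_trials():
    """Ten short five-class trials of one subject (enough for the 7:1:2
    trial-level split machinery)."""
    return generate_dataset(1, 10, QUICK_CLASSES, seed=11, trial_duration_s=6)
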