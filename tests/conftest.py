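import numpy as np
import pytest

from nervetrace.core import Calibration
from nervetrace.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def native_cal() -> Calibration:
    return Calibration(400.0, 384)


@pytest.fixture(scope="session")
def small_phantom():
    """One clean 128-px phantom (no cells, no noise) shared across tests."""
    cfg = PhantomConfig(
        size_px=128, n_nerves=(3, 5), n_cells=(0, 0), noise_sigma=0.0,
        fade_period_px=80.0,
    )
    return generate_phantom(cfg, seed=42, image_id="fixture")


@pytest.fixture(scope="session")
def noisy_phantom():
    """One realistic 128-px phantom with confounders and noise."""
    cfg = PhantomConfig(size_px=128, fade_period_px=80.0, n_cells=(3, 8))
    return generate_phantom(cfg, seed=7, image_id="fixture_noisy")
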