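import numpy as np
import pytest

import sersquant as sq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_thiram():
    """Deterministic thiram config: no noise, default baseline."""
    return sq.thiram_config(noise_rsd=0.0, seed=0)


@pytest.fixture
def clean_thiram():
    """Deterministic thiram config with no noise and no background."""
    return sq.thiram_config(
        noise_rsd=0.0, baseline_amplitude=0.0, baseline_offset=0.0, seed=0
    )


@pytest.fixture
def small_set():
    """Tiny two-spectrum set on a 5-point axis."""
    nu = np.array([550.0, 551.0, 552.0, 553.0, 554.0])
    return sq.SpectrumSet(
        nu,
        np.array([[1.0, 3.0, 5.0, 7.0, 9.0], [3.0, 5.0, 7.0, 9.0, 11.0]]),
        ["a", "b"],
        np.array([0.5, 1.5]),
        "ug/mL",
        ["g1", "g1"],
    )
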