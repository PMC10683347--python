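import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import raman_dbc as rd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_spectrum(rng):
    w = 600.0 + np.arange(501.0)
    return rd.Spectrum(w, rng.normal(10.0, 3.0, w.size))


@pytest.fixture(scope="session")
def base_config():
    return rd.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Short-axis, short-run configuration for fast IO/CLI tests."""
    return rd.SynthConfig(
        seed=5, wn_lo=1500.0, wn_hi=1800.0, load_volume_mL=40.0, v_mid_mL=20.0
    )


@pytest.fixture(scope="session")
def study():
    """One full synthetic study, shared across tests that only read it."""
    return rd.run_synthetic_study(0)
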