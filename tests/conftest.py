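import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitcsm import SynthConfig, generate_walk, label_series, load_example_model

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_walk():
    """A clean 5-cycle trace: speed 4 km/h -> 1500 ms cycles, 7.5 s."""
    cfg = SynthConfig(
        speed_kmh=4.0, duration_s=7.5, noise_sd=0.0, spike_rate_per_s=0.0, seed=11
    )
    series, truth = generate_walk(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def labeled_noisy_walk():
    """A realistic noisy trace with its reference four-phase tracks."""
    cfg = SynthConfig(speed_kmh=4.0, duration_s=15.0, seed=7)
    series, truth = generate_walk(cfg)
    tracks = label_series(series)
    return series, truth, tracks


@pytest.fixture(scope="session")
def example_model():
    return load_example_model()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
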