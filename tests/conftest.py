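import numpy as np
import pytest

from vegniche.drivers import (
    DriverSignal,
    SyntheticDriverConfig,
    generate_synthetic_drivers,
)
from vegniche.fixtures import example_parameter_table
from vegniche.niche import default_class_key


@pytest.fixture(scope="session")
def class_key():
    return default_class_key()


@pytest.fixture(scope="session")
def example_table():
    return example_parameter_table()


def constant_signals(**overrides):
    """Driver signals with no seasonality, trend or noise (constant series),
    selectively overridable per driver."""
    base = {
        "pH": DriverSignal(baseline=4.3),
        "N": DriverSignal(baseline=1.2),
        "moisture": DriverSignal(baseline=0.55),
        "soil_temp": DriverSignal(baseline=10.0),
        "floor_light": DriverSignal(baseline=0.12),
    }
    base.update(overrides)
    return base


@pytest.fixture()
def constant_drivers():
    """Three years of perfectly constant single-layer drivers."""
    cfg = SyntheticDriverConfig(
        start_year=2000,
        n_years=3,
        layers=(("L", 0.0, 0.3),),
        signals=constant_signals(),
        seed=0,
    )
    return generate_synthetic_drivers(cfg), cfg.profile


@pytest.fixture()
def noisy_drivers():
    """Default synthetic drivers (seasonal cycle, trend, noise), 3 years."""
    cfg = SyntheticDriverConfig(start_year=2000, n_years=3, seed=42)
    return generate_synthetic_drivers(cfg), cfg.profile


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
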