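import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import firspec as fs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> fs.SyntheticConfig:
    """The emulated study conditions: 5 groups x 36 seedlings, 512-band grid."""
    return fs.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(default_config) -> fs.SpectraSet:
    return fs.simulate_dataset(default_config)


@pytest.fixture(scope="session")
def small_grid() -> fs.WavelengthGrid:
    """A 64-band grid for fast pipeline-level tests."""
    return fs.WavelengthGrid(np.linspace(870.0, 1720.0, 64))


@pytest.fixture(scope="session")
def small_dataset(small_grid) -> fs.SpectraSet:
    cfg = fs.SyntheticConfig(seed=5, n_per_group=8, grid=small_grid)
    return fs.simulate_dataset(cfg)
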