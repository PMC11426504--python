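import numpy as np
import pytest

from fluctstock.operating_model import (
    ObservationError,
    OperatingModelConfig,
    simulate_season,
)


@pytest.fixture(scope="session")
def noise_free_season():
    """One noise-free season from the default (pulsed) operating model."""
    cfg = OperatingModelConfig(rng_seed=5,
                               obs_error=ObservationError(0.0, 0.0))
    table, truth = simulate_season(80_000.0, cfg, seed=42)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
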