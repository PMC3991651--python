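import numpy as np
import pytest

from gutmix.lbm_flow import SimulationConfig
from gutmix.pendular_synth import PendularConfig, generate_strain_rate_map


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Coarse half-length channel used by fast solver tests (square lattice:
    nx/ny fixed by the 25:1 length-to-half-width ratio at 5 cm)."""
    return SimulationConfig(length=0.05, nx=125, ny=5, duration=120.0)


@pytest.fixture(scope="session")
def short_map() -> "StrainRateMap":
    return generate_strain_rate_map(
        PendularConfig(n_domains=4, amplitude=0.4, duration=60.0, seed=11)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
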