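import numpy as np
import pytest

from tetraschool import InteractionParams, KickStatistics, SimulationConfig


@pytest.fixture
def default_params() -> InteractionParams:
    """Experimentally fitted pair parameters."""
    return InteractionParams()


@pytest.fixture
def sweep_params() -> InteractionParams:
    """Parameters of the 100-fish phase-diagram experiments."""
    return InteractionParams(gamma_att=0.04, gamma_ali=0.2, l_att=0.28, l_ali=0.28, k=1)


@pytest.fixture
def fixed_kicks() -> KickStatistics:
    return KickStatistics(mode="fixed")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_fish=3,
        params=InteractionParams(gamma_att=0.04, gamma_ali=0.2, l_att=0.28, l_ali=0.28, k=1),
        gamma_r=0.1,
        kick_stats=KickStatistics(mode="fixed"),
        n_kicks_per_fish=50,
        transient_seconds=0.0,
        sampling_dt=1.0,
        seed=42,
        record_kicks=True,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
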