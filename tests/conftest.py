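import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from peepflow.simulate import (
    AnimalParams,
    NoiseConfig,
    Recruitment,
    SimConfig,
    generate_acquisition,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

QUIET_NOISE = NoiseConfig(p_ao=0.0, p_eso=0.0, p_ga=0.0, flow=0.0, edi=0.0, eit=0.0)


def neutral_animal() -> AnimalParams:
    """An animal with all random effects at their population values."""
    return AnimalParams(
        animal_id=1, vt_scale=1.0, rr_scale=1.0, c_lung_scale=1.0,
        r_aw_scale=1.0, peak_paw_scale=1.0, recruitment=Recruitment(),
    )


@pytest.fixture(scope="session")
def quiet_config() -> SimConfig:
    """Noise-free simulator configuration for oracle-grade checks."""
    return SimConfig(seed=0, duration=20.0, noise=QUIET_NOISE)


@pytest.fixture(scope="session")
def quiet_acquisition_peep0(quiet_config):
    rng = np.random.default_rng(0)
    return generate_acquisition(quiet_config, neutral_animal(), 0.0, "incremental", rng)


@pytest.fixture(scope="session")
def quiet_acquisition_peep15(quiet_config):
    rng = np.random.default_rng(0)
    return generate_acquisition(quiet_config, neutral_animal(), 15.0, "incremental", rng)


@pytest.fixture(scope="session")
def small_cohort():
    """Two animals over a short incremental/decremental ladder, with noise."""
    from peepflow.simulate import generate_protocol_dataset

    config = SimConfig(
        seed=11, n_animals=2, duration=12.0, peep_ladder=(0, 9, 15, 9, 0)
    )
    return config, generate_protocol_dataset(config)
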