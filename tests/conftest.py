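import numpy as np
import pytest

from glymphwave.preprocess import BoldSession
from glymphwave.synthetic import SimulationConfig, generate_parcellation, generate_session


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Default-physics session config at a reduced parcel count."""
    return SimulationConfig(n_parcels=80)


@pytest.fixture(scope="session")
def parcellation80():
    return generate_parcellation(80, seed=11)


@pytest.fixture(scope="session")
def session_and_truth(small_config, parcellation80):
    return generate_session(small_config, parcellation=parcellation80, seed=7)


@pytest.fixture()
def noise_session() -> BoldSession:
    """A pure-noise session (no global events) for null-case behavior."""
    rng = np.random.default_rng(123)
    n_t = 140
    return BoldSession(
        bold=rng.standard_normal((12, n_t)),
        csf=rng.standard_normal(n_t),
        motion=np.zeros((n_t, 6)),
        tr=3.0,
    )


@pytest.fixture(scope="session")
def cohort_tiny():
    from glymphwave.synthetic import generate_cohort

    cfg = SimulationConfig(
        n_parcels=80, stage_counts=(5, 6, 5), followup_counts=(3, 5, 3)
    )
    return generate_cohort(cfg, seed=21)
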