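import numpy as np
import pytest

from jackmr.simulate import SimulationParams, simulate_scenario_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """A desk-sized scenario: strong enough genetics that liberal thresholds
    select SNPs, small enough that a full pipeline runs in milliseconds."""
    return SimulationParams(
        n_applied=800,
        n_external=800,
        n_snp=40,
        n_block=4,
        thresholds=(1e-3, 0.05, 1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_pair(small_params):
    rng = np.random.default_rng(small_params.seed)
    return simulate_scenario_pair(small_params, rng)
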