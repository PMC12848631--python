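import numpy as np
import pytest

from cpmtrial.simulate import (
    ConnectomeSimConfig,
    TrialSimConfig,
    simulate_connectome_cohort,
    simulate_trial,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted-effect cohort (60 subjects, 60 nodes, 15+15 edges)."""
    return simulate_connectome_cohort(ConnectomeSimConfig(seed=1))


@pytest.fixture(scope="session")
def planted_edge_matrix(planted_cohort):
    return planted_cohort.edge_matrix()


@pytest.fixture(scope="session")
def small_trial():
    """Complete-data trial (no missingness or dropout), 20 per arm."""
    return simulate_trial(
        TrialSimConfig(n_per_arm=20, missing_day_prob=0.0, dropout_prob=0.0, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
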