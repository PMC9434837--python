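import numpy as np
import pytest

from citepipe import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.default_config(
        seed=7, n_participants_per_group=2, cells_per_participant=400
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """3,200-cell cohort: 4 groups x 2 participants x 400 cells, 7.5% doublets."""
    return synthetic.generate_cohort(small_config)


@pytest.fixture(scope="session")
def midsize_cohort():
    """~5,000 singlet-scale cohort for detector recall / gating accuracy checks."""
    config = synthetic.default_config(
        seed=11, n_participants_per_group=1, cells_per_participant=1250
    )
    return synthetic.generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
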