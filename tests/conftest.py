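import numpy as np
import pytest

from latedating.dating_equations import default_equations
from latedating.synthetic_cohort import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def equations():
    return default_equations()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticCohortConfig(n_per_site=150, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A modest three-site cohort shared across read-only tests."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def spared_cohort():
    """Cohort with the cerebellum fully protected from growth restriction."""
    cfg = SyntheticCohortConfig(n_per_site=600, seed=7, sparing_factor=1.0)
    scans, births = generate_cohort(cfg)
    return cfg, scans, births


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
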