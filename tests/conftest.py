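import numpy as np
import pytest

from musclemap import CohortModel, GeneratorConfig


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort_model(default_config):
    """Resolved sampling model; construction is deterministic and reusable."""
    return CohortModel(default_config)


@pytest.fixture(scope="session")
def small_cohort(cohort_model):
    return cohort_model.sample(60, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
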