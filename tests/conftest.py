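import numpy as np
import pytest
from hypothesis import settings

from spascreen.cohort import default_study_specs, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_specs():
    return default_study_specs()


@pytest.fixture(scope="session")
def default_cohort(default_specs):
    """The default three-group cohort at the canonical seed."""
    groups, items = default_specs
    return generate_cohort(groups, items, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
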