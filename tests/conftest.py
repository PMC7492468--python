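import numpy as np
import pytest

import discnet as dn
from discnet.pipeline import reduce_dataset, trait_tables


@pytest.fixture(scope="session")
def default_dataset():
    """One full default study (seed 1): 48 animals minus 2 exclusions."""
    return dn.generate_study(dn.StudyConfig(seed=1))


@pytest.fixture(scope="session")
def default_reduced(default_dataset):
    return reduce_dataset(default_dataset)


@pytest.fixture(scope="session")
def default_tables(default_dataset, default_reduced):
    return trait_tables(default_dataset, default_reduced)


@pytest.fixture(scope="session")
def small_study_kwargs():
    """Cheap trace settings for tests that do not reduce biomechanics."""
    return dict(n_cycles=2, trace_sampling_hz=20.0,
                creep_duration_s=120.0, creep_sampling_hz=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
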