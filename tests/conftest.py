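import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sgbayes import datasets

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def stampede():
    return datasets.stampede_estimates()


@pytest.fixture(scope="session")
def meteor():
    return datasets.meteor_estimates()


@pytest.fixture(scope="session")
def elicited_grid():
    return datasets.elicited_joint_grid()


@pytest.fixture(scope="session")
def partition():
    return datasets.default_partition()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
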