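import numpy as np
import pytest
from hypothesis import settings

from ectoloc import (
    build_conduction_graph,
    compute_times_matrix,
    generate_heart,
    generate_torso,
    solid_angle_transfer,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_heart():
    """Coarse ventricle (~340 nodes) for fast unit tests."""
    return generate_heart(n_subdiv=2, seed=0)


@pytest.fixture(scope="session")
def small_torso(small_heart):
    return generate_torso(small_heart, n_electrodes=32, standoff=40.0, seed=0)


@pytest.fixture(scope="session")
def small_transfer(small_heart, small_torso):
    return solid_angle_transfer(small_heart, small_torso)


@pytest.fixture(scope="session")
def small_times(small_heart):
    return compute_times_matrix(build_conduction_graph(small_heart))


@pytest.fixture(scope="session")
def study_heart():
    """Default-resolution ventricle (~750 nodes) for the full-search studies."""
    return generate_heart(n_subdiv=3, seed=0)


@pytest.fixture(scope="session")
def study_torso(study_heart):
    return generate_torso(study_heart, n_electrodes=64, standoff=40.0, seed=0)


@pytest.fixture(scope="session")
def study_transfer(study_heart, study_torso):
    return solid_angle_transfer(study_heart, study_torso)


@pytest.fixture(scope="session")
def study_times(study_heart):
    return compute_times_matrix(build_conduction_graph(study_heart))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
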