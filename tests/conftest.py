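import pytest
from hypothesis import settings

from ovitherm import synthetic
from ovitherm.cohort import Condition

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def full_experiment():
    """One default-parameter factorial experiment (24 conditions, 480 clusters)."""
    params = synthetic.GeneratorParams(seed=0)
    observations, fates = synthetic.generate_experiment(params=params)
    return observations, fates, params


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced experiment for fast structural checks."""
    params = synthetic.GeneratorParams(seed=11)
    observations, fates = synthetic.generate_experiment(
        clusters_per_condition=3, eggs_per_cluster_range=(5, 8), params=params
    )
    return observations, fates, params


@pytest.fixture()
def medium_design():
    return [Condition(t, "medium") for t in synthetic.DEFAULT_TEMPERATURES_C]
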