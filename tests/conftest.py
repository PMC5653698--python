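import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_profiles():
    from siptrflp import datasets

    return datasets.reference_profiles()


@pytest.fixture(scope="session")
def profiles_by_condition(reference_profiles):
    return {p.condition_label: p for p in reference_profiles}


@pytest.fixture(scope="session")
def clone_predictions():
    from siptrflp import datasets

    return datasets.clone_predictions()


@pytest.fixture(scope="session")
def observed_trfs():
    from siptrflp import datasets

    return datasets.observed_trfs()


@pytest.fixture(scope="session")
def simulated_pair():
    """One labeled/unlabeled condition pair at a fixed seed."""
    from siptrflp import study

    return study.condition_pair(seed=1)
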