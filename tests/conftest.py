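import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Two-block (8-male) synthetic study shared across tests."""
    from fiddlerwave.simulate import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(n_blocks=2), seed=42)


@pytest.fixture(scope="session")
def small_hmm_data(small_study):
    from fiddlerwave.hmm import prepare_hmm_data
    from fiddlerwave.simulate import study_intervals

    return prepare_hmm_data(study_intervals(small_study), small_study.metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
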