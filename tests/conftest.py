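import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from attnstates import simulate  # noqa: E402


@pytest.fixture(scope="session")
def design():
    return simulate.ExperimentDesign()


@pytest.fixture(scope="session")
def gen_model():
    return simulate.default_generative_model()


@pytest.fixture(scope="session")
def small_cohort(gen_model):
    """Six participants, ten blocks: big enough for every downstream stage."""
    design = simulate.ExperimentDesign(n_blocks=10)
    return simulate.simulate_cohort(gen_model, design, 6, master_seed=424242)


@pytest.fixture(scope="session")
def small_trials(small_cohort):
    return simulate.cohort_trials(small_cohort)


@pytest.fixture(scope="session")
def small_probes(small_cohort):
    return simulate.cohort_probes(small_cohort)
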