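import numpy as np
import pytest

from agegap import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast pipeline-level tests."""
    return generate_cohort(GeneratorConfig(n_subjects=4000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
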