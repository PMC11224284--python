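import numpy as np
import pytest

from tcrscreen import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
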