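
import numpy as np
import pytest

from exwas import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete-data cohort with planted effects, reused read-only."""
    spec = synth.default_spec(
        seed=11, n_planted=6, beta_range=(1.5, 3.0), n_subjects=1200, n_variables=60,
        missing_rate=0.0
    )
    return synth.generate_exposome(spec)


@pytest.fixture(scope="session")
def missing_cohort():
    """Small cohort with MAR missingness and partner structure."""
    spec = synth.default_spec(
        seed=7, n_planted=6, beta_range=(1.5, 3.0), n_subjects=1000, n_variables=60,
        missing_rate=0.15
    )
    return synth.generate_exposome(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
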