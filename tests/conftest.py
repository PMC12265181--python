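import numpy as np
import pytest

from brainsym.synthetic import CohortParams, PhantomParams, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Exactly mirror-symmetric full-size phantom."""
    img, truth = make_phantom(PhantomParams())
    return img


@pytest.fixture(scope="session")
def small_cohort_params():
    """Modest cohort size for fast SEM unit tests."""
    return CohortParams(n_subjects=500, seed=7)
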