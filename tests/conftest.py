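import numpy as np
import pytest

from cuffseg.phantom import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def default_case():
    """One deterministic default-grid phantom, shared across tests."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-case cohort covering all tear categories, shared across tests."""
    return generate_cohort(6, PhantomSpec(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
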