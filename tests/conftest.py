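import numpy as np
import pytest

from alphaconvert import synthgen
from alphaconvert.config import CohortConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One full default cohort (with source maps), shared across tests."""
    return synthgen.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def lean_cohort():
    """Default-parameter cohort without source maps (fast path)."""
    return synthgen.generate_cohort(CohortConfig(include_maps=False), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
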