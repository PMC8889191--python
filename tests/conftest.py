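import numpy as np
import pytest

from beeswarmsim import generate_stimulus_set
from beeswarmsim.pipeline import generate_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_stimuli():
    """Eight-trial stimulus set (4 true / 4 null), deterministic."""
    return generate_stimulus_set(8, 0.5, np.random.default_rng(7))


@pytest.fixture(scope="session")
def fixtures():
    """The packaged small fixture bundle (stimuli, cohort, quiz key, sheets)."""
    return generate_fixtures(seed=42)
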