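import numpy as np
import pytest

from hrvnoise import CohortSpec, generate_cohort, sample_segments


@pytest.fixture(scope="session")
def small_cohort():
    """Four short synthetic recordings (default physiology)."""
    return generate_cohort(CohortSpec(n_recordings=4, duration=480.0, seed=11))


@pytest.fixture(scope="session")
def one_segment(small_cohort):
    return sample_segments(small_cohort, 1, seed=3)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
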