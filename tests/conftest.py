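import numpy as np
import pytest

from cogedkit.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-participant paperlike cohort with exclusions present."""
    return generate_cohort(CohortConfig(n_participants=24, seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    """A 40-participant cohort with no exclusions and low choice noise."""
    cfg = CohortConfig(
        n_participants=40,
        seed=11,
        p_no_headphones=0.0,
        p_incomplete=0.0,
        softmax_temperature=0.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
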