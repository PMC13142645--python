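import numpy as np
import pytest

from fcbag.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small multi-site case-control cohort with a 5-year case shift."""
    cfg = SyntheticConfig(
        n_subjects=120, n_regions=12, n_timepoints=80, n_sites=2,
        case_fraction=0.3, bag_shift_years=5.0, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
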