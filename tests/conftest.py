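import numpy as np
import pytest

from painprint.preprocess import PreprocessConfig, preprocess_cohort
from painprint.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small 2-class cohort reused across tests (4/group, triplicates)."""
    cfg = CohortConfig(n_per_group=4, seed=42)
    spectra, blanks, behavior, truth = generate_cohort(cfg)
    return spectra, blanks, behavior, truth


@pytest.fixture(scope="session")
def small_peaklists(small_cohort):
    spectra, blanks, behavior, truth = small_cohort
    peaklists, blank_pls = preprocess_cohort(spectra, blanks, PreprocessConfig())
    return peaklists, blank_pls, behavior, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
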