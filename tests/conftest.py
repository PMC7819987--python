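import numpy as np
import pytest

from fuzzyct import (
    CohortParams,
    generate_cohort,
    generate_phantom_suite,
    segment_hematomas,
    detect_fuzzy_sign,
)


@pytest.fixture(scope="session")
def small_suite():
    """Two phantoms per scenario; shared across imaging tests."""
    return generate_phantom_suite(2, seed=7)


@pytest.fixture(scope="session")
def small_suite_detections(small_suite):
    """Segmentations and sign evidence for the shared suite."""
    out = []
    for vol, truth in small_suite:
        comps = segment_hematomas(vol)
        out.append((vol, truth, comps, detect_fuzzy_sign(vol, comps)))
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated development-sized cohort."""
    return generate_cohort(CohortParams(), seed=3)


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort for distributional checks."""
    return generate_cohort(CohortParams(n_patients=20000), seed=5)
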