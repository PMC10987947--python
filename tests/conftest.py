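import numpy as np
import pytest

from emgkin import signal_prep as sp
from emgkin.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """Smallest cohort that exercises the full grid."""
    return SyntheticCohortSpec(n_subjects=2, n_movements=2, trial_duration_s=3.0,
                               shift_magnitude=1.0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_spec):
    return generate_cohort(tiny_cohort_spec, master_seed=7)


@pytest.fixture(scope="session")
def tiny_feature_series(tiny_cohort):
    """Mu-law features for one subject of the tiny cohort."""
    recs = [r for r in tiny_cohort.recordings if r.subject_id == "S01"]
    norm = sp.fit_normalization([sp.raw_rms(r) for r in recs])
    return [sp.prepare_features(r, norm) for r in recs]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
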