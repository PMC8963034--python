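import numpy as np
import pytest

from emgfuse import pipeline as pl
from emgfuse.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast cohort configuration used across unit tests."""
    return CohortConfig(
        n_subjects=4, n_positions=2, n_repetitions=3,
        hold_s=1.0, rest_s=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return generate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_recording(tiny_cohort):
    return tiny_cohort[0][1][0]


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    """Fused feature matrices per subject, ground-truth segmentation."""
    return {
        prof.subject_id: pl.subject_feature_matrix(recs, segmentation="true")
        for prof, recs in tiny_cohort
    }
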