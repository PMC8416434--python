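"""Shared fixtures: small synthetic cohorts and recordings.

Expensive cohort fixtures are session-scoped so the suite pays for
generation and feature extraction once.
"""

import numpy as np
import pytest

from qeeg import (
    CohortConfig,
    EFFECT_PRESETS,
    ModelSpec,
    Recording,
    generate_cohort,
)
from qeeg.pipeline import extract_records

RATE = 128.0


def make_recording(data, subject_id="sub", rate=RATE):
    return Recording(subject_id=subject_id, data=np.asarray(data, float), rate=rate)


def white_recording(seed=0, duration_s=60.0, scale=1.0, rate=RATE):
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate)
    return make_recording(scale * rng.standard_normal((19, n)), f"white{seed}")


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale model spec: shorter penalty path and 3 inner folds."""
    return ModelSpec(seed=7, inner_cv_folds=3, en_n_lambdas=15, en_tol=1e-5)


@pytest.fixture(scope="session")
def null_cohort():
    """20+20 subjects, no group effect."""
    cc = CohortConfig(n_cases=20, n_controls=20, seed=42)
    recs, covs = generate_cohort(cc)
    return recs, covs


@pytest.fixture(scope="session")
def null_records(null_cohort):
    recs, covs = null_cohort
    return extract_records(recs), covs


@pytest.fixture(scope="session")
def alpha_cohort():
    """30+30 subjects with the posterior alpha-power effect."""
    cc = CohortConfig(n_cases=30, n_controls=30, seed=21)
    recs, covs = generate_cohort(cc, EFFECT_PRESETS["alpha_power"])
    return recs, covs


@pytest.fixture(scope="session")
def alpha_records(alpha_cohort):
    recs, covs = alpha_cohort
    return extract_records(recs), covs
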