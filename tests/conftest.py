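import numpy as np
import pytest

import riskrasch as rr
from riskrasch.reference import (
    ENDORSEMENT_COUNTS,
    ITEM_DIFFICULTIES,
    ITEM_DIFFICULTY_SES,
    SAMPLE_SIZE,
)

#: Published raw-score → (measure, SE) conversion for the 9-item scale.
PUBLISHED_SCORE_TABLE = {
    0: (-5.71, 1.99),
    1: (-4.02, 1.32),
    2: (-2.53, 1.16),
    3: (-1.26, 1.08),
    4: (-0.19, 0.99),
    5: (0.73, 0.93),
    6: (1.58, 0.93),
    7: (2.47, 0.97),
    8: (3.58, 1.17),
    9: (5.03, 1.91),
}


@pytest.fixture(scope="session")
def published_difficulties():
    return np.asarray(ITEM_DIFFICULTIES)


@pytest.fixture(scope="session")
def published_ses():
    return np.asarray(ITEM_DIFFICULTY_SES)


@pytest.fixture(scope="session")
def published_matrix():
    """Deterministic 351×9 matrix whose column totals equal the published
    endorsement counts (row order is irrelevant for margins)."""
    X = np.zeros((SAMPLE_SIZE, 9))
    for i, k in enumerate(ENDORSEMENT_COUNTS):
        X[:k, i] = 1.0
    return rr.ResponseMatrix(
        X,
        person_ids=[f"P{n}" for n in range(SAMPLE_SIZE)],
        item_labels=list(rr.reference.ITEM_LABELS),
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic cohort at the study conditions (N=351, calibrated pop)."""
    return rr.simulate_responses(rr.PopulationSpec(seed=11))


@pytest.fixture(scope="session")
def study_fit(study_cohort):
    return rr.fit_jmle(study_cohort.matrix)


def bisect_measure(difficulties, target, lo=-60.0, hi=60.0, tol=1e-12):
    """Independent bisection solver for sum_i P(theta, d_i) = target."""
    d = np.asarray(difficulties, dtype=float)

    def f(th):
        return (1.0 / (1.0 + np.exp(-(th - d)))).sum() - target

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
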