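import warnings

import pytest

from ppaudit.cohort import generate_cohort


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # hard-margin SVC on tiny permuted label sets occasionally warns about
    # non-separability; that is expected behaviour under permutation
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="training data not linearly separable")
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """One study-condition cohort (direct outcomes, no staircase noise)."""
    cohort, truth = generate_cohort(seed=0)
    return cohort, truth
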