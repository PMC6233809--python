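import numpy as np
import pytest

from tastepe.cohort import CohortSpec
from tastepe.reward_task import RWModel, compute_pe_trace, generate_trial_sequence


@pytest.fixture(scope="session")
def default_sequence():
    return generate_trial_sequence(16, 16, 16, p_violation=0.2, seed=11)


@pytest.fixture(scope="session")
def default_trace(default_sequence):
    return compute_pe_trace(default_sequence, RWModel(alpha=0.7))


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Reduced cohort: large enough for an 18-column multivariate test."""
    return CohortSpec(n_an=14, n_control=12, seed=21)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_spec):
    from tastepe.cohort import simulate_cohort

    return simulate_cohort(small_cohort_spec)
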