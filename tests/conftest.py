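import numpy as np
import pytest

from labourprogress.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort for pipeline-level tests."""
    config = CohortConfig(n_women=800, seed=11)
    women, exams = simulate_cohort(config)
    return women, exams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
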