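import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across pipeline tests."""
    from recallmix.simulate import CohortSpec, generate_cohort

    spec = CohortSpec(n_subjects=16, trials_low=25, trials_high=60, seed=20)
    trials, subjects, truth = generate_cohort(spec)
    return spec, trials, subjects, truth


@pytest.fixture(scope="session")
def small_estimates(small_cohort):
    from recallmix.pipeline import fit_cohort

    _, trials, _, _ = small_cohort
    return fit_cohort(trials, n_starts=6, n_chance_reps=2000, seed=5)


def bessel_i0_series(x, terms=60):
    """Independent power-series oracle for the modified Bessel function I0."""
    import math

    return sum((x / 2.0) ** (2 * k) / math.factorial(k) ** 2 for k in range(terms))


def bessel_i1_series(x, terms=60):
    """Independent power-series oracle for I1."""
    import math

    return sum(
        (x / 2.0) ** (2 * k + 1) / (math.factorial(k) * math.factorial(k + 1))
        for k in range(terms)
    )
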