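import numpy as np
import pytest

from ivim3b import (
    BRAIN,
    AcquisitionScheme,
    CohortSpec,
    NoiseSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def scheme_300():
    return AcquisitionScheme.two_point(300.0)


@pytest.fixture(scope="session")
def scheme_500():
    return AcquisitionScheme.two_point(500.0)


@pytest.fixture(scope="session")
def f_grid():
    return np.round(np.linspace(0.06, 0.30, 13), 2)


def closed_form_fit(model, f, b_low, b_high=1000.0):
    """Independent two-point oracle: direct log/exp arithmetic on the
    bi-exponential forward values, no code under test involved."""
    import math

    def S(b):
        return f * math.exp(-b * model.D_star) + (1 - f) * math.exp(-b * model.D)

    span = b_high - b_low
    D = math.log(S(b_low) / S(b_high)) / span
    ln_int = (b_high * math.log(S(b_low)) - b_low * math.log(S(b_high))) / span
    f_est = 1.0 - math.exp(ln_int)  # noise-free S(0) = 1
    return D, f_est


@pytest.fixture(scope="session")
def oracle():
    return closed_form_fit


@pytest.fixture(scope="session")
def default_cohort():
    """One shared synthetic cohort at study defaults (16 subjects, 4 repeats)."""
    return generate_cohort(CohortSpec(seed=20260925))
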