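import numpy as np
import pytest

from brcacost import default_parameters
from brcacost.cohort import PatientProfile


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def tested_patient():
    """Modal reference patient: diagnosed at 40, counseled and tested,
    mid-range complication risk, with a private event stream."""
    return PatientProfile(40, True, True, 0.15,
                          event_seed=np.random.SeedSequence(1234))


@pytest.fixture
def untested_patient():
    return PatientProfile(40, False, False, 0.15,
                          event_seed=np.random.SeedSequence(99))


def zero_hazard_params(params, discount=None):
    """Degenerate configuration: every stochastic event switched off.

    Keeps tariffs and follow-up so closed-form cost arithmetic applies.
    """
    ps = params.copy()
    for key in ("radiotherapy_after_mastectomy", "radiotherapy_after_quadrantectomy",
                "recurrence_detection", "positive_biopsy", "residual_gland_carcinoma"):
        ps.probabilities[key] = 0.0
    for table in (ps.new_incidence_risk, ps.contralateral_risk):
        table.brackets = [(lo, hi, 0.0) for lo, hi, _ in table.brackets]
    if discount is not None:
        ps.engine.discount_rate = discount
    return ps.validate()


@pytest.fixture
def degenerate_params(params):
    return zero_hazard_params(params)
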