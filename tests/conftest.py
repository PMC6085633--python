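import numpy as np
import pytest

from batcea.calibration import CalibrationSpec, calibrate
from batcea.effectiveness import load_packaged_score_model
from batcea.lifetable import MAX_AGE, LifeTable, default_life_tables
from batcea.params import ModelParameters


@pytest.fixture(scope="session")
def life_tables():
    return default_life_tables()


@pytest.fixture()
def params():
    """Fresh default parameter set (mutable per test)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def calibrated(life_tables):
    """Calibrated parameter set shared across tests (treat as read-only)."""
    return calibrate(CalibrationSpec(), ModelParameters(), life_tables)


@pytest.fixture(scope="session")
def score_model():
    return load_packaged_score_model()


@pytest.fixture(scope="session")
def zero_background_tables():
    """Life tables with no background mortality (isolates NYHA excess)."""
    qx = np.zeros(MAX_AGE + 1)
    qx[MAX_AGE] = 1.0
    return {
        "male": LifeTable(sex="male", qx=qx.copy()),
        "female": LifeTable(sex="female", qx=qx.copy()),
    }


def null_effect_params() -> ModelParameters:
    """BAT made indistinguishable from OMT: unit RRs, zero device costs."""
    from batcea.params import CostParam, RelativeRisk

    p = ModelParameters()
    p.rr_mortality = RelativeRisk(1.0, 1e-6)
    p.rr_hosp = RelativeRisk(1.0, 1e-6)
    for f in ("cost_system", "cost_battery", "cost_implant_proc",
              "cost_replacement_proc", "cost_visits", "cost_short_term_ae",
              "cost_long_term_ae"):
        setattr(p.device, f, CostParam(0.0))
    p.device.p_short_term_ae.value = 0.0
    p.device.p_procedural_death = 0.0
    return p


@pytest.fixture()
def null_params():
    return null_effect_params()
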