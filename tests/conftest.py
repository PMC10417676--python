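import numpy as np
import pytest

from nnose import (
    PatientRecord,
    PlateAssay,
    Response,
    SimulationConfig,
    Stage,
    Timepoint,
)

#: Response-class composition of the reference 30-patient cohort.
COHORT_CLASS_COUNTS = {"CR": 3, "PR": 20, "SD": 6, "PD": 1}


def make_patient(pid, response, excluded_reason=None, **kw):
    defaults = dict(
        age=70, sex="M", c_t="3", c_n="1", c_m="0", stage=Stage.III,
    )
    defaults.update(kw)
    return PatientRecord(
        patient_id=pid,
        response=Response.parse(response) if isinstance(response, str) else response,
        excluded_reason=excluded_reason,
        **defaults,
    )


@pytest.fixture
def reference_cohort():
    """30 patients with the reference class mix 3/20/6/1 CR/PR/SD/PD."""
    patients = []
    i = 0
    for cls, n in COHORT_CLASS_COUNTS.items():
        for _ in range(n):
            i += 1
            patients.append(make_patient(f"P{i:03d}", cls))
    return patients


@pytest.fixture
def plate():
    return PlateAssay(
        patient_id="P001",
        timepoint=Timepoint.T1_PRE_TREATMENT,
        plate_id="P001-T1-p1",
        n_urine=30,
        n_control=10,
        n_elsewhere=60,
    )


@pytest.fixture
def default_config():
    return SimulationConfig(seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
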