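import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ttebench as tb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_bundle(patients=None, enrollment=None, dispensings=None,
                diagnoses=None, deaths=None) -> tb.ClaimsBundle:
    """Hand-written bundle helper: missing tables default to empty."""
    def df(data, columns):
        if data is None:
            return pd.DataFrame(columns=columns)
        return pd.DataFrame(data, columns=columns)

    return tb.ClaimsBundle(
        patients=df(patients, ["patient_id", "birth_year", "sex", "region"]),
        enrollment=df(enrollment, ["patient_id", "span_start_day", "span_end_day"]),
        dispensings=df(dispensings, ["patient_id", "drug_code", "fill_day", "days_supply"]),
        diagnoses=df(diagnoses, ["patient_id", "code", "day", "setting"]),
        deaths=df(deaths, ["patient_id", "death_day"]),
    )


@pytest.fixture
def toy_bundle():
    """Six hand-written patients: 2 fail washout, 1 fails enrollment, 3 pass.

    Patients 1 (comparator, day 400), 2 (exposure, day 420) and 6
    (exposure, day 410) are eligible.  Patient 3 indexes at day 400 but
    has an enrollment gap inside the pre-index year.  Patients 4 and 5
    have a same-class fill inside their washout window.
    """
    patients = [(i, 1958 + i, "F", "south") for i in range(1, 7)]
    enrollment = [(1, 0, 1400), (2, 0, 1400), (3, 0, 200), (3, 210, 1400),
                  (4, 0, 1400), (5, 0, 1400), (6, 0, 1400)]
    E, C, S = "RX_EXPO", "RX_COMP", "RX_CLASS1"
    dispensings = [
        (1, C, 400, 30), (1, C, 430, 30),
        (2, E, 420, 30),
        (3, E, 400, 30),
        (4, S, 100, 30), (4, E, 400, 30),   # gap 300 < washout 365
        (5, S, 200, 30), (5, C, 450, 30),   # gap 250 < washout 365
        (6, E, 410, 30),
    ]
    return make_bundle(patients=patients, enrollment=enrollment,
                       dispensings=dispensings)


@pytest.fixture(scope="session")
def small_generated_bundle():
    """One seeded confounded database, small n, for structural invariants."""
    cfg = tb.scenario("confounded_benefit", n_patients=3000)
    return cfg, tb.generate_population(cfg)[0]


def followup_records(rows):
    """Build a follow-up record frame from (arm, time, status) tuples."""
    return pd.DataFrame(
        [(i, arm, t, status, None, None) for i, (arm, t, status) in enumerate(rows)],
        columns=["patient_id", "arm", "time", "status", "event_component",
                 "censor_reason"])
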