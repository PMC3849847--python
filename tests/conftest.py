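"""Shared fixtures: a small deterministic synthetic dataset and helpers."""

import pandas as pd
import pytest

from comorbval import SimulationConfig, build_cohort, generate_linked_data

SMALL_N = {"ICD9": 150, "ICD10": 200}


def make_admission(person_id="p1", admission_id="a1",
                   admission_date="1998-03-01", separation_date=None,
                   icd_version=9, principal_diagnosis="4109",
                   secondary_diagnoses="", admission_type="emergency",
                   hospital_type="public", hospital_location="metropolitan",
                   transfer_in=0, transfer_out=0, died_in_hospital=0,
                   indigenous_flag=0) -> dict:
    """One admission row with sensible defaults, for hand-built histories."""
    if separation_date is None:
        separation_date = admission_date
    return dict(person_id=person_id, admission_id=admission_id,
                admission_date=admission_date,
                separation_date=separation_date, icd_version=icd_version,
                principal_diagnosis=principal_diagnosis,
                secondary_diagnoses=secondary_diagnoses,
                admission_type=admission_type, hospital_type=hospital_type,
                hospital_location=hospital_location, transfer_in=transfer_in,
                transfer_out=transfer_out, died_in_hospital=died_in_hospital,
                indigenous_flag=indigenous_flag)


def admissions_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([make_admission(**r) for r in rows])


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_patients_per_era=dict(SMALL_N), seed=20260928)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_linked_data(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_dataset):
    adm, mr, truth = small_dataset
    return build_cohort(adm, mr, small_config.era_windows, truth=truth)
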