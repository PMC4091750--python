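from datetime import date

import pytest

from pipscreen.codebook import load_bundled_codebook
from pipscreen.model import Diagnosis, Patient, PatientRecord, Prescription, StudyWindow
from pipscreen.rules import load_bundled_rule_pack

WINDOW = StudyWindow(start=date(2007, 1, 1), end=date(2008, 1, 1), leadin_days=90)


@pytest.fixture(scope="session")
def codebook():
    return load_bundled_codebook()


@pytest.fixture(scope="session")
def pack():
    return load_bundled_rule_pack()


@pytest.fixture(scope="session")
def pack28(pack):
    return pack.subset()


@pytest.fixture
def window():
    return WINDOW


def make_patient(pid="P1", sex="female", birth_year=1930, reg_start=date(2000, 1, 1), reg_end=None):
    return Patient(
        patient_id=pid,
        sex=sex,
        birth_year=birth_year,
        registration_start=reg_start,
        registration_end=reg_end,
    )


def make_rx(pid, drug_code, issue, *, strength, daily_units=1.0, days=28):
    return Prescription(
        patient_id=pid,
        drug_code=drug_code,
        issue_date=issue,
        strength=strength,
        quantity=days * daily_units,
        daily_units=daily_units,
    )


def make_record(prescriptions=(), diagnoses=(), **patient_kwargs):
    patient = make_patient(**patient_kwargs)
    return PatientRecord(
        patient=patient,
        prescriptions=[p for p in prescriptions],
        diagnoses=[d for d in diagnoses],
    )


def make_dx(pid, code, when):
    return Diagnosis(patient_id=pid, condition_code=code, event_date=when)
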