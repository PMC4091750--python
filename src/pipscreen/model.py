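"""Typed in-memory model of CPRD-style flat tables.

Three delimited-text tables describe a primary-care cohort:

* ``patient.csv`` — ``patient_id, sex, birth_year, registration_start,
  registration_end`` (registration_end may be blank for open registrations);
* ``therapy.csv`` — ``patient_id, drug_code, issue_date, strength, quantity,
  daily_units, duration_days`` (duration_days may be blank; it is then derived
  as ``ceil(quantity / daily_units)``);
* ``clinical.csv`` — ``patient_id, condition_code, event_date``.

Dates are ISO-8601; every interval in the package is closed on the start and
open on the end (``[start, end)``). Age is computed from birth year only,
evaluated at the study-window start, mirroring the coarse granularity of
primary-care research databases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

SEXES = ("male", "female", "missing")

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "registration_start", "registration_end"]
THERAPY_COLUMNS = ["patient_id", "drug_code", "issue_date", "strength", "quantity", "daily_units", "duration_days"]
CLINICAL_COLUMNS = ["patient_id", "condition_code", "event_date"]


class SchemaError(ValueError):
    """A mandatory column is missing or a cell cannot be parsed."""


@dataclass(frozen=True)
class StudyWindow:
    """Cross-sectional study window with a lead-in history requirement.

    ``start`` .. ``end`` is the observation window, ``[start, end)``.
    ``leadin_days`` is the minimum history required before ``start`` so that
    long-term-use rules can be assessed (90 days by default, i.e. three
    months of lead-in data).
    """

    start: date
    end: date
    leadin_days: int = 90

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("StudyWindow start must be <= end")
        if self.leadin_days < 0:
            raise ValueError("leadin_days must be >= 0")

    @property
    def leadin_start(self) -> date:
        return self.start - timedelta(days=self.leadin_days)

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str
    birth_year: int
    registration_start: date
    registration_end: date | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    def age_at(self, when: date) -> int:
        return when.year - self.birth_year


@dataclass(frozen=True)
class Prescription:
    patient_id: str
    drug_code: str
    issue_date: date
    strength: float
    quantity: float
    daily_units: float
    duration_days: int | None = None

    def __post_init__(self) -> None:
        if self.strength <= 0 or self.quantity <= 0 or self.daily_units <= 0:
            raise ValueError("strength, quantity and daily_units must be > 0")
        if self.duration_days is not None and self.duration_days <= 0:
            raise ValueError("duration_days must be > 0 when given")

    @property
    def effective_duration_days(self) -> int:
        if self.duration_days is not None:
            return self.duration_days
        return math.ceil(self.quantity / self.daily_units)

    @property
    def coverage_end(self) -> date:
        return self.issue_date + timedelta(days=self.effective_duration_days)

    @property
    def total_mass(self) -> float:
        """Total active ingredient dispensed (strength x quantity)."""
        return self.strength * self.quantity


@dataclass(frozen=True)
class Diagnosis:
    patient_id: str
    condition_code: str
    event_date: date


@dataclass
class PatientRecord:
    """One subject: demographics plus date-stamped prescriptions and diagnoses."""

    patient: Patient
    prescriptions: list[Prescription] = field(default_factory=list)
    diagnoses: list[Diagnosis] = field(default_factory=list)

    @property
    def patient_id(self) -> str:
        return self.patient.patient_id


Cohort = dict[str, PatientRecord]


def eligible(patient: Patient, window: StudyWindow, min_age: int = 70) -> bool:
    """Age >= min_age at window start and registration covering the lead-in.

    Patients still registered at window start are retained even if they
    later transfer out mid-window.
    """
    if patient.age_at(window.start) < min_age:
        return False
    if patient.registration_start > window.leadin_start:
        return False
    if patient.registration_end is not None and patient.registration_end < window.start:
        return False
    return True


def _parse_dates(frame: pd.DataFrame, column: str, path: str) -> pd.Series:
    parsed = pd.to_datetime(frame[column], format="%Y-%m-%d", errors="coerce")
    bad = frame[column].notna() & parsed.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise SchemaError(f"{path}: unparseable date {frame[column][bad.idxmax()]!r} in column {column!r} at line {line}")
    return parsed.dt.date


def _require_columns(frame: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {', '.join(missing)}")


def read_cohort(
    patient_path: str | Path,
    therapy_path: str | Path,
    clinical_path: str | Path,
    window: StudyWindow,
    min_age: int = 70,
) -> Cohort:
    """Read the three tables and return one :class:`PatientRecord` per eligible patient.

    Eligibility: age >= ``min_age`` at ``window.start`` (from birth year) and
    registration starting no later than ``window.start - leadin_days``.
    Counts of excluded patients and of orphan therapy/clinical rows are logged.
    """
    patients = pd.read_csv(patient_path, dtype={"patient_id": str, "sex": str})
    _require_columns(patients, PATIENT_COLUMNS[:4], str(patient_path))
    if "registration_end" not in patients.columns:
        patients["registration_end"] = pd.NA
    patients["registration_start"] = _parse_dates(patients, "registration_start", str(patient_path))
    patients["registration_end"] = _parse_dates(patients, "registration_end", str(patient_path))

    cohort: Cohort = {}
    n_excluded = 0
    for row in patients.itertuples(index=False):
        sex = row.sex if isinstance(row.sex, str) and row.sex in SEXES else "missing"
        patient = Patient(
            patient_id=str(row.patient_id),
            sex=sex,
            birth_year=int(row.birth_year),
            registration_start=row.registration_start,
            registration_end=None if pd.isna(row.registration_end) else row.registration_end,
        )
        if eligible(patient, window, min_age=min_age):
            cohort[patient.patient_id] = PatientRecord(patient=patient)
        else:
            n_excluded += 1
    if n_excluded:
        log.info("read_cohort: excluded %d patient(s) failing age/registration checks", n_excluded)

    therapy = pd.read_csv(therapy_path, dtype={"patient_id": str, "drug_code": str})
    _require_columns(therapy, THERAPY_COLUMNS[:6], str(therapy_path))
    if "duration_days" not in therapy.columns:
        therapy["duration_days"] = pd.NA
    therapy["issue_date"] = _parse_dates(therapy, "issue_date", str(therapy_path))
    n_orphan = 0
    for row in therapy.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in cohort:
            n_orphan += 1
            continue
        cohort[pid].prescriptions.append(
            Prescription(
                patient_id=pid,
                drug_code=str(row.drug_code),
                issue_date=row.issue_date,
                strength=float(row.strength),
                quantity=float(row.quantity),
                daily_units=float(row.daily_units),
                duration_days=None if pd.isna(row.duration_days) else int(row.duration_days),
            )
        )
    clinical = pd.read_csv(clinical_path, dtype={"patient_id": str, "condition_code": str})
    _require_columns(clinical, CLINICAL_COLUMNS, str(clinical_path))
    clinical["event_date"] = _parse_dates(clinical, "event_date", str(clinical_path))
    for row in clinical.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in cohort:
            n_orphan += 1
            continue
        cohort[pid].diagnoses.append(
            Diagnosis(patient_id=pid, condition_code=str(row.condition_code), event_date=row.event_date)
        )
    if n_orphan:
        log.info("read_cohort: dropped %d therapy/clinical row(s) of non-cohort patients", n_orphan)

    for record in cohort.values():
        record.prescriptions.sort(key=lambda p: (p.issue_date, p.drug_code))
        record.diagnoses.sort(key=lambda d: (d.event_date, d.condition_code))
    return cohort


def cohort_frames(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The cohort as (patient, therapy, clinical) DataFrames in file column order."""
    pat_rows = []
    rx_rows = []
    dx_rows = []
    for record in cohort.values():
        p = record.patient
        pat_rows.append(
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_year": p.birth_year,
                "registration_start": p.registration_start.isoformat(),
                "registration_end": "" if p.registration_end is None else p.registration_end.isoformat(),
            }
        )
        for rx in record.prescriptions:
            rx_rows.append(
                {
                    "patient_id": rx.patient_id,
                    "drug_code": rx.drug_code,
                    "issue_date": rx.issue_date.isoformat(),
                    "strength": rx.strength,
                    "quantity": rx.quantity,
                    "daily_units": rx.daily_units,
                    "duration_days": "" if rx.duration_days is None else rx.duration_days,
                }
            )
        for dx in record.diagnoses:
            dx_rows.append(
                {
                    "patient_id": dx.patient_id,
                    "condition_code": dx.condition_code,
                    "event_date": dx.event_date.isoformat(),
                }
            )
    return (
        pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS),
        pd.DataFrame(rx_rows, columns=THERAPY_COLUMNS),
        pd.DataFrame(dx_rows, columns=CLINICAL_COLUMNS),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables; ``read_cohort`` on the result reproduces the cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, therapy, clinical = cohort_frames(cohort)
    paths = {
        "patient": out / "patient.csv",
        "therapy": out / "therapy.csv",
        "clinical": out / "clinical.csv",
    }
    patients.to_csv(paths["patient"], index=False)
    therapy.to_csv(paths["therapy"], index=False)
    clinical.to_csv(paths["clinical"], index=False)
    return paths
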