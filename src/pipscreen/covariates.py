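"""Regression covariates: repeat medication, polypharmacy, age band, Charlson.

Definitions follow the study conventions: a *repeat medication* is a drug
class with three or more prescriptions issued inside the study window;
*polypharmacy* is four or more repeat medications from different drug
groups. The Charlson comorbidity index is the classic 17-category weighted
sum (weights 1/2/3/6) over distinct categories coded on or before the
assessment date; no age points are added because age enters the regression
as its own covariate. Covariate derivation is window-local: prescriptions
outside the window never affect repeat counts (lead-in history matters only
for criterion durations).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codebook import UNKNOWN, Codebook
from .model import Cohort, Diagnosis, Prescription, StudyWindow
from datetime import date

AGE_BANDS = ("70-74", "75-80", "81-85", ">85")
CHARLSON_BANDS = ("1", "2", "3")

#: Raw-score to band mapping used by the cohort tables: 0-1 -> "1",
#: exactly 2 -> "2", 3 or more -> "3".
DEFAULT_CHARLSON_BANDING = {"1": (0, 1), "2": (2, 2), "3": (3, None)}


@dataclass(frozen=True)
class CovariateRow:
    patient_id: str
    polypharmacy: bool
    n_repeat_classes: int
    age_band: str
    sex: str
    charlson_score: int
    charlson_band: str


def repeat_medications(
    prescriptions: list[Prescription], codebook: Codebook, window: StudyWindow
) -> set[str]:
    """Drug classes with >= 3 prescriptions issued within the window."""
    counts: dict[str, int] = {}
    for rx in prescriptions:
        if not (window.start <= rx.issue_date < window.end):
            continue
        drug_class = codebook.resolve_class(rx.drug_code)
        if drug_class == UNKNOWN:
            continue
        counts[drug_class] = counts.get(drug_class, 0) + 1
    return {c for c, n in counts.items() if n >= 3}


def polypharmacy_flag(repeat_classes: set[str]) -> bool:
    """Four or more repeat medications, each from a different drug group."""
    return len(repeat_classes) >= 4


def charlson_score(diagnoses: list[Diagnosis], codebook: Codebook, as_of_date: date) -> int:
    """Weighted sum over distinct Charlson categories coded on or before the date."""
    categories: dict[str, int] = {}
    for dx in diagnoses:
        if dx.event_date > as_of_date:
            continue
        hit = codebook.charlson(dx.condition_code)
        if hit is not None:
            category, weight = hit
            categories[category] = weight
    return sum(categories.values())


def age_band(birth_year: int, window: StudyWindow) -> str:
    age = window.start.year - birth_year
    if age < 70:
        raise ValueError(f"age {age} below cohort minimum")
    if age <= 74:
        return "70-74"
    if age <= 80:
        return "75-80"
    if age <= 85:
        return "81-85"
    return ">85"


def charlson_band(score: int, banding: dict[str, tuple[int, int | None]] = DEFAULT_CHARLSON_BANDING) -> str:
    for label, (low, high) in banding.items():
        if score >= low and (high is None or score <= high):
            return label
    raise ValueError(f"charlson score {score} not covered by banding {banding}")


def derive_covariates(cohort: Cohort, codebook: Codebook, window: StudyWindow) -> pd.DataFrame:
    """One covariate row per patient, assessed at the window start."""
    rows = []
    for patient_id in sorted(cohort):
        record = cohort[patient_id]
        repeats = repeat_medications(record.prescriptions, codebook, window)
        score = charlson_score(record.diagnoses, codebook, as_of_date=window.start)
        rows.append(
            {
                "patient_id": patient_id,
                "polypharmacy": polypharmacy_flag(repeats),
                "n_repeat_classes": len(repeats),
                "age_band": age_band(record.patient.birth_year, window),
                "sex": record.patient.sex,
                "charlson_score": score,
                "charlson_band": charlson_band(score),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "polypharmacy",
            "n_repeat_classes",
            "age_band",
            "sex",
            "charlson_score",
            "charlson_band",
        ],
    )
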