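"""Independent day-by-day screening oracle.

Materialises daily exposure sets from the drug eras and tests each criterion
predicate literally on every calendar day of the study window, with no
interval algebra. Used to cross-check the engine's closed-form evaluator;
kept deliberately naive and separate from the implementation.
"""

from __future__ import annotations

from datetime import timedelta

from pipscreen.codebook import Codebook
from pipscreen.engine import DrugEra, build_drug_eras
from pipscreen.model import PatientRecord, StudyWindow
from pipscreen.rules import CriterionDef, RulePack


def _covers(era: DrugEra, day) -> bool:
    return era.era_start <= day < era.era_end


def _dose_ok(era: DrugEra, criterion: CriterionDef) -> bool:
    if criterion.dose is None:
        return True
    value = era.avg_ddd_per_day if criterion.dose.units == "ddd_per_day" else era.avg_mass_per_day
    return criterion.dose.passes(value)


def _condition_present(record, codebook, concepts, day, window_days):
    for dx in record.diagnoses:
        if codebook.resolve_concept(dx.condition_code) not in concepts:
            continue
        if dx.event_date > day:
            continue
        if window_days is not None and (day - dx.event_date).days > window_days:
            continue
        return True
    return False


def oracle_criterion(
    record: PatientRecord,
    criterion: CriterionDef,
    class_eras: list[DrugEra],
    window: StudyWindow,
    codebook: Codebook,
):
    """First window day on which the predicate holds literally, else None."""
    if criterion.sex_restriction and record.patient.sex != criterion.sex_restriction:
        return None
    qualifying = [
        e for e in class_eras if e.drug_class in criterion.target_drugs and _dose_ok(e, criterion)
    ]
    co_eras = [e for e in class_eras if e.drug_class in criterion.co_drugs_required]
    protective_eras = [e for e in class_eras if e.drug_class in criterion.protective_co_drugs]

    cumulative = 0
    day = window.leadin_start
    while day < window.end:
        exposed = any(_covers(e, day) for e in qualifying)
        if exposed:
            cumulative += 1
        if day >= window.start and exposed:
            ok = True
            if criterion.co_drugs_required and not any(_covers(e, day) for e in co_eras):
                ok = False
            if ok and any(_covers(e, day) for e in protective_eras):
                ok = False
            if ok and criterion.required_conditions and not _condition_present(
                record, codebook, set(criterion.required_conditions), day, criterion.condition_window_days
            ):
                ok = False
            if ok:
                for concept in criterion.required_conditions_all:
                    if not _condition_present(record, codebook, {concept}, day, criterion.condition_window_days):
                        ok = False
                        break
            if ok and criterion.excluded_conditions and _condition_present(
                record, codebook, set(criterion.excluded_conditions), day, None
            ):
                ok = False
            if ok and criterion.min_duration_days is not None and cumulative <= criterion.min_duration_days:
                ok = False
            if ok:
                return day
        day += timedelta(days=1)
    return None


def oracle_duplication(
    record: PatientRecord,
    criterion: CriterionDef,
    code_eras: list[DrugEra],
    window: StudyWindow,
    codebook: Codebook,
):
    """Brute-force pairwise overlap day count; earliest day the floor is met."""
    best = None
    grouped = [(e, codebook.duplication_group(e.key)) for e in code_eras]
    grouped = [(e, g) for e, g in grouped if g is not None]
    for i, (era_a, group_a) in enumerate(grouped):
        for era_b, group_b in grouped[i + 1 :]:
            if era_a.key == era_b.key or group_a != group_b:
                continue
            count = 0
            day = window.start
            while day < window.end:
                if _covers(era_a, day) and _covers(era_b, day):
                    count += 1
                    if count == criterion.min_overlap_days:
                        if best is None or day < best:
                            best = day
                        break
                day += timedelta(days=1)
    return best


def oracle_screen_record(
    record: PatientRecord,
    pack: RulePack,
    codebook: Codebook,
    window: StudyWindow,
    max_gap_days: int = 30,
) -> dict[str, object]:
    """criterion_id -> first trigger date, for every criterion that fires."""
    class_eras = build_drug_eras(record.prescriptions, codebook, max_gap_days, level="class")
    code_eras = build_drug_eras(record.prescriptions, codebook, max_gap_days, level="code")
    out = {}
    for criterion in pack:
        if criterion.is_duplication:
            trigger = oracle_duplication(record, criterion, code_eras, window, codebook)
        else:
            trigger = oracle_criterion(record, criterion, class_eras, window, codebook)
        if trigger is not None:
            out[criterion.criterion_id] = trigger
    return out
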