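"""Temporal STOPP criterion evaluation over drug exposure eras.

Exposure is modelled as *drug eras*: per-patient, per-class (or per-code)
continuous intervals built by merging the coverage of consecutive
prescriptions separated by at most ``max_gap_days``. A criterion fires for a
patient on the first calendar day inside the study window on which its whole
predicate holds; each (patient, criterion) pair yields at most one event,
matching the patient-level "number of patients" accounting used in
prevalence tables.

Predicate semantics, applied day by day (the interval algebra here is an
exact closed form of that day scan):

* drug exposure — a target-class era covers the day (dose rules only count
  eras whose era-average daily dose passes the threshold);
* required conditions — coded on or before the day (within the rule's
  recency window if one is set, e.g. a fall in the prior 90 days);
* excluded conditions — never coded on or before the day;
* co-prescription — calendar-day overlap with a required co-class era;
* protective co-prescription — overlap with a protective class era
  suppresses the rule on that day (e.g. gastroprotection);
* duration — cumulative qualifying exposure days since the start of the
  lead-in period strictly exceed the threshold;
* therapeutic duplication — two eras of *different* drug codes sharing a
  duplication group overlap at least ``min_overlap_days`` within the window
  (shorter overlaps are treated as switch artifacts and do not fire).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

from . import intervals as iv
from .codebook import UNKNOWN, Codebook
from .model import Cohort, PatientRecord, Prescription, StudyWindow
from .rules import CriterionDef, RulePack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugEra:
    """A continuous exposure interval with era-average daily dose."""

    patient_id: str
    key: str                 # drug class (level='class') or drug code (level='code')
    drug_class: str
    era_start: date
    era_end: date            # exclusive
    total_ddd: float
    total_mass: float
    n_prescriptions: int

    def __post_init__(self) -> None:
        if self.era_start >= self.era_end:
            raise ValueError("era_start must be < era_end")

    @property
    def days(self) -> int:
        return (self.era_end - self.era_start).days

    @property
    def avg_ddd_per_day(self) -> float:
        return self.total_ddd / self.days

    @property
    def avg_mass_per_day(self) -> float:
        return self.total_mass / self.days

    def interval(self) -> iv.Interval:
        return (self.era_start, self.era_end)


@dataclass(frozen=True)
class PIPEvent:
    patient_id: str
    criterion_id: str
    first_trigger_date: date
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class EngineConfig:
    max_gap_days: int = 30
    duplication_min_overlap_days: int | None = None  # None = rule's own value


def build_drug_eras(
    prescriptions: list[Prescription],
    codebook: Codebook,
    max_gap_days: int = 30,
    level: str = "class",
) -> list[DrugEra]:
    """Merge prescription coverage into eras per drug class or per drug code.

    Consecutive prescriptions of the same key whose coverage intervals are
    separated by at most ``max_gap_days`` merge into one era. DDD and mass
    totals accumulate over the era; unknown drug codes are skipped with a
    warning.
    """
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    if level not in ("class", "code"):
        raise ValueError("level must be 'class' or 'code'")
    gap = timedelta(days=max_gap_days)

    by_key: dict[str, list[Prescription]] = {}
    for rx in sorted(prescriptions, key=lambda p: (p.issue_date, p.drug_code)):
        drug_class = codebook.resolve_class(rx.drug_code)
        if drug_class == UNKNOWN:
            continue
        key = drug_class if level == "class" else rx.drug_code
        by_key.setdefault(key, []).append(rx)

    eras: list[DrugEra] = []
    for key, rxs in sorted(by_key.items()):
        drug_class = codebook.resolve_class(rxs[0].drug_code)
        start = end = None
        ddd_sum = mass_sum = 0.0
        n = 0

        def flush() -> None:
            if start is not None:
                eras.append(
                    DrugEra(
                        patient_id=rxs[0].patient_id,
                        key=key,
                        drug_class=drug_class,
                        era_start=start,
                        era_end=end,
                        total_ddd=ddd_sum,
                        total_mass=mass_sum,
                        n_prescriptions=n,
                    )
                )

        for rx in rxs:
            ddd_amount = codebook.ddd_amount(rx.drug_code)
            rx_ddd = rx.total_mass / ddd_amount if ddd_amount else 0.0
            if start is None:
                start, end = rx.issue_date, rx.coverage_end
                ddd_sum, mass_sum, n = rx_ddd, rx.total_mass, 1
            elif rx.issue_date <= end + gap:
                end = max(end, rx.coverage_end)
                ddd_sum += rx_ddd
                mass_sum += rx.total_mass
                n += 1
            else:
                flush()
                start, end = rx.issue_date, rx.coverage_end
                ddd_sum, mass_sum, n = rx_ddd, rx.total_mass, 1
        flush()
    return eras


def _condition_days(
    record: PatientRecord,
    codebook: Codebook,
    concepts: tuple[str, ...],
    window_days: int | None,
) -> iv.DaySet:
    """Days on which any of the concepts counts as present."""
    out: iv.DaySet = []
    for dx in record.diagnoses:
        if codebook.resolve_concept(dx.condition_code) in concepts:
            if window_days is None:
                out.append((dx.event_date, iv.DATE_MAX))
            else:
                out.append((dx.event_date, dx.event_date + timedelta(days=window_days + 1)))
    return iv.normalize(out)


def _class_days(eras: list[DrugEra], classes: tuple[str, ...]) -> iv.DaySet:
    return iv.normalize([e.interval() for e in eras if e.drug_class in classes])


def evaluate_criterion(
    record: PatientRecord,
    criterion: CriterionDef,
    eras: list[DrugEra],
    window: StudyWindow,
    codebook: Codebook,
) -> list[PIPEvent]:
    """Zero or one event: the first window day on which the predicate holds."""
    if criterion.is_duplication:
        raise ValueError("duplication criteria are handled by detect_duplication")
    if criterion.sex_restriction and record.patient.sex != criterion.sex_restriction:
        return []

    target = [e for e in eras if e.drug_class in criterion.target_drugs]
    if criterion.dose is not None:
        dose_units = criterion.dose.units
        target = [
            e
            for e in target
            if criterion.dose.passes(e.avg_ddd_per_day if dose_units == "ddd_per_day" else e.avg_mass_per_day)
        ]
    if not target:
        return []
    qualifying = iv.normalize([e.interval() for e in target])

    eligible = iv.clip(qualifying, window.start, window.end)

    if criterion.co_drugs_required:
        eligible = iv.intersect(eligible, _class_days(eras, criterion.co_drugs_required))
    if criterion.protective_co_drugs:
        eligible = iv.difference(eligible, _class_days(eras, criterion.protective_co_drugs))

    if criterion.required_conditions:
        eligible = iv.intersect(
            eligible,
            _condition_days(record, codebook, criterion.required_conditions, criterion.condition_window_days),
        )
    for concept in criterion.required_conditions_all:
        eligible = iv.intersect(
            eligible,
            _condition_days(record, codebook, (concept,), criterion.condition_window_days),
        )
    if criterion.excluded_conditions:
        excluded_dates = [
            dx.event_date
            for dx in record.diagnoses
            if codebook.resolve_concept(dx.condition_code) in criterion.excluded_conditions
        ]
        if excluded_dates:
            eligible = iv.intersect(eligible, [(iv.DATE_MIN, min(excluded_dates))])

    if criterion.min_duration_days is not None:
        # cumulative qualifying exposure days over lead-in + window; fires
        # strictly above the threshold, i.e. on the (T+1)-th exposure day
        counted = iv.clip(qualifying, window.leadin_start, window.end)
        crossing = iv.nth_day(counted, criterion.min_duration_days + 1)
        if crossing is None:
            return []
        eligible = iv.intersect(eligible, [(crossing, iv.DATE_MAX)])

    trigger = iv.first_day(eligible)
    if trigger is None:
        return []
    evidence = tuple(
        f"era:{e.key}:{e.era_start.isoformat()}:{e.era_end.isoformat()}" for e in target
    )
    return [
        PIPEvent(
            patient_id=record.patient_id,
            criterion_id=criterion.criterion_id,
            first_trigger_date=trigger,
            evidence=evidence,
        )
    ]


def detect_duplication(
    record: PatientRecord,
    code_eras: list[DrugEra],
    duplication_groups: dict[str, str],
    min_overlap_days: int,
    window: StudyWindow,
    criterion: CriterionDef,
) -> list[PIPEvent]:
    """Concurrent use of two distinct agents from one therapeutic group.

    Fires on the day the within-window overlap of a pair of eras (different
    drug codes, same duplication group) reaches ``min_overlap_days``.
    """
    if min_overlap_days < 1:
        raise ValueError("min_overlap_days must be >= 1")
    grouped = [e for e in code_eras if duplication_groups.get(e.key)]
    best: date | None = None
    evidence: tuple[str, ...] = ()
    for i, era_a in enumerate(grouped):
        for era_b in grouped[i + 1 :]:
            if era_a.key == era_b.key:
                continue
            if duplication_groups[era_a.key] != duplication_groups[era_b.key]:
                continue
            overlap = iv.clip(
                iv.intersect([era_a.interval()], [era_b.interval()]),
                window.start,
                window.end,
            )
            trigger = iv.nth_day(overlap, min_overlap_days)
            if trigger is not None and (best is None or trigger < best):
                best = trigger
                evidence = (
                    f"era:{era_a.key}:{era_a.era_start.isoformat()}:{era_a.era_end.isoformat()}",
                    f"era:{era_b.key}:{era_b.era_start.isoformat()}:{era_b.era_end.isoformat()}",
                )
    if best is None:
        return []
    return [
        PIPEvent(
            patient_id=record.patient_id,
            criterion_id=criterion.criterion_id,
            first_trigger_date=best,
            evidence=evidence,
        )
    ]


@dataclass
class ScreenResult:
    """Per-patient PIP events for one cohort / rule-pack run."""

    events: list[PIPEvent] = field(default_factory=list)
    n_patients: int = 0

    @property
    def events_by_patient(self) -> dict[str, list[PIPEvent]]:
        out: dict[str, list[PIPEvent]] = {}
        for event in self.events:
            out.setdefault(event.patient_id, []).append(event)
        return out

    def criteria_fired(self, patient_id: str) -> set[str]:
        return {e.criterion_id for e in self.events if e.patient_id == patient_id}

    def patients_with_any(self) -> set[str]:
        return {e.patient_id for e in self.events}

    def count_per_criterion(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for event in self.events:
            out[event.criterion_id] = out.get(event.criterion_id, 0) + 1
        return out


def screen_record(
    record: PatientRecord,
    pack: RulePack,
    codebook: Codebook,
    window: StudyWindow,
    config: EngineConfig = EngineConfig(),
) -> list[PIPEvent]:
    class_eras = build_drug_eras(record.prescriptions, codebook, config.max_gap_days, level="class")
    code_eras = build_drug_eras(record.prescriptions, codebook, config.max_gap_days, level="code")
    groups = {
        code: group
        for code in {e.key for e in code_eras}
        if (group := codebook.duplication_group(code)) is not None
    }
    events: list[PIPEvent] = []
    for criterion in pack:
        if criterion.is_duplication:
            overlap = config.duplication_min_overlap_days or criterion.min_overlap_days
            events.extend(
                detect_duplication(record, code_eras, groups, overlap, window, criterion)
            )
        else:
            events.extend(evaluate_criterion(record, criterion, class_eras, window, codebook))
    return events


def screen_cohort(
    cohort: Cohort,
    pack: RulePack,
    codebook: Codebook,
    window: StudyWindow,
    config: EngineConfig = EngineConfig(),
) -> ScreenResult:
    """Apply every criterion to every patient; deterministic given inputs."""
    result = ScreenResult(n_patients=len(cohort))
    for patient_id in sorted(cohort):
        result.events.extend(screen_record(cohort[patient_id], pack, codebook, window, config))
    return result
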