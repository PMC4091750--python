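"""Seeded generator of CPRD-shaped cohorts with planted, truth-labelled PIP.

The generator emulates an age >=70 primary-care population observed over a
12-month window with at least three months of lead-in history: age-band and
sex frequencies follow the cohort-table marginals of the source population,
chronic conditions are coded before the window at configurable prevalences,
and repeat-prescription streams use a 28-day issue cadence.

Planting is *constructive*: a planted criterion is realised by concrete
prescription and diagnosis rows built to satisfy the rule's predicate (dose
rules exceed their threshold by a sampled margin, duration rules by at least
7 days, drug-disease rules code the condition before the drug era), and then
*engine-verified* at generation time, so the generator and the screening
engine cannot silently disagree. Background prescriptions draw only on drug
classes no criterion references, so patients with nothing planted can never
fire a rule. Optional near-miss injection places just-below-threshold
exposure (2 scripts where 3 make a repeat, overlaps one day short of
duplication, doses at a strict threshold) to stress rule boundaries.

When ``true_coefficients`` is set the generator links planting to covariates
through a logistic model: polypharmacy, age band, sex and Charlson band are
assigned first, the PIP outcome is drawn from the stated log-odds, and
positive patients receive one plantable criterion — giving a cohort with
known regression truth for parameter-recovery checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .codebook import Codebook, load_bundled_codebook
from .covariates import age_band
from .engine import EngineConfig, build_drug_eras, detect_duplication, evaluate_criterion, screen_record
from .model import Cohort, Diagnosis, Patient, PatientRecord, Prescription, StudyWindow, write_cohort
from .rules import CriterionDef, RulePack, load_bundled_rule_pack

DEFAULT_WINDOW = StudyWindow(start=date(2007, 1, 1), end=date(2008, 1, 1), leadin_days=90)

#: Age-band sampling weights matching the source cohort's marginal structure.
DEFAULT_AGE_WEIGHTS = {"70-74": 0.215, "75-80": 0.242, "81-85": 0.185, ">85": 0.358}
DEFAULT_SEX_WEIGHTS = {"male": 0.41, "female": 0.58, "missing": 0.01}

#: Chronic-condition prevalences, roughly matching the cohort table of the
#: emulated population where reported and plausible elsewhere.
DEFAULT_CONDITION_PREVALENCES = {
    "cond:copd": 0.034,
    "cond:peptic_ulcer": 0.068,
    "cond:diabetes": 0.165,
    "cond:dementia": 0.024,
    "cond:hypertension": 0.347,
    "cond:osteoarthritis": 0.197,
    "cond:heart_failure": 0.011,
    "cond:parkinsonism": 0.019,
    "cond:gout": 0.02,
    "cond:glaucoma": 0.02,
    "cond:constipation": 0.05,
    "cond:epilepsy": 0.01,
    "cond:cardiac_conduction": 0.01,
    "cond:prostatism": 0.03,
    "cond:urinary_retention": 0.01,
    "cond:incontinence": 0.02,
    "cond:urinary_catheter_long_term": 0.01,
    "cond:ankle_oedema": 0.03,
    "cond:fall": 0.03,
    "cond:hypoglycaemia": 0.005,
    "cond:coronary_disease": 0.08,
    "cond:mi": 0.05,
    "cond:cerebrovascular": 0.04,
    "cond:pvd": 0.025,
    "cond:renal_failure": 0.02,
    "cond:cancer": 0.04,
    "cond:metastatic_tumour": 0.005,
    "cond:liver_disease_mild": 0.005,
    "cond:liver_disease_severe": 0.002,
    "cond:rheumatoid_arthritis": 0.03,
    "cond:hemiplegia": 0.005,
    "cond:diabetes_complications": 0.02,
}

#: Criteria safe for outcome-linked planting: their drugs and conditions
#: touch neither the Charlson categories nor each other's predicates.
OUTCOME_PLANTABLE = (
    "dup_therapeutic_duplication",
    "cns_benzo_long_term",
    "cns_antihistamine_prolonged",
    "cv_thiazide_gout",
    "cv_digoxin_high_dose",
    "cns_tca_constipation",
)

#: Log-odds used by outcome-linked planting; exponentials mirror the
#: adjusted associations of the emulated study.
DEFAULT_TRUE_COEFFICIENTS = {
    "const": -1.8,
    "polypharmacy[ever]": math.log(18.2),
    "age_band[75-80]": math.log(0.9),
    "age_band[81-85]": math.log(0.8),
    "age_band[>85]": math.log(0.4),
    "sex[female]": math.log(0.9),
    "sex[missing]": math.log(1.5),
    "charlson_band[2]": math.log(1.51),
    "charlson_band[3]": math.log(0.9),
}

BACKGROUND_CLASSES = (
    "class:levothyroxine",
    "class:bisphosphonate",
    "class:paracetamol",
    "class:metformin",
    "class:calcium_vitd",
    "class:inhaled_beta_agonist",
)
# class:metformin background scripts never code diabetes; Charlson input is
# the clinical table only, so this cannot shift the comorbidity score.

AGE_RANGES = {"70-74": (70, 74), "75-80": (75, 80), "81-85": (81, 85), ">85": (86, 95)}


class PlantingError(RuntimeError):
    """A planted criterion cannot be realised or failed engine verification."""


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    n_patients: int = 500
    seed: int = 0
    window: StudyWindow = DEFAULT_WINDOW
    age_band_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_WEIGHTS))
    sex_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_WEIGHTS))
    condition_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCES)
    )
    planting_rates: dict[str, float] = field(default_factory=dict)
    background_intensity: float = 2.0        # mean background repeat classes per patient
    near_miss_rate: float = 0.0
    true_coefficients: dict[str, float] | None = None
    charlson_band_weights: dict[str, float] = field(
        default_factory=lambda: {"1": 0.659, "2": 0.110, "3": 0.231}
    )
    polypharmacy_rate: float = 0.23          # outcome-linked mode only
    verify: str = "full"                     # "full" | "planted"

    def validate(self, pack: RulePack) -> None:
        for name, weights in (("age_band_weights", self.age_band_weights), ("sex_weights", self.sex_weights)):
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise SimConfigError(f"{name} must sum to 1")
        known = set(pack.ids)
        for criterion_id, rate in self.planting_rates.items():
            if criterion_id not in known:
                raise SimConfigError(f"planting rate for unknown criterion {criterion_id!r}")
            if not 0.0 <= rate <= 1.0:
                raise SimConfigError(f"planting rate for {criterion_id} outside [0, 1]")
        for prob in self.condition_prevalences.values():
            if not 0.0 <= prob <= 1.0:
                raise SimConfigError("condition prevalences must lie in [0, 1]")
        if self.verify not in ("full", "planted"):
            raise SimConfigError("verify must be 'full' or 'planted'")


def default_planting_rates(pack: RulePack) -> dict[str, float]:
    """Study-like planting: duplication and unindicated aspirin most common,
    inappropriate PPI next, a low base rate elsewhere."""
    rates = {c.criterion_id: 0.005 for c in pack}
    rates.update(
        {
            "dup_therapeutic_duplication": 0.10,
            "cv_aspirin_no_indication": 0.08,
            "gi_ppi_max_dose_8w": 0.03,
            "uri_alpha_blocker_catheter": 0.03,
        }
    )
    return {k: v for k, v in rates.items() if k in set(pack.ids)}


@dataclass
class PatientTruth:
    planted: list[str] = field(default_factory=list)
    expected: list[str] = field(default_factory=list)
    polypharmacy: bool = False
    charlson_band: str = "1"
    any_pip: bool = False


@dataclass
class TruthLabels:
    per_patient: dict[str, PatientTruth] = field(default_factory=dict)

    def planted_events(self) -> set[tuple[str, str]]:
        return {
            (pid, cid) for pid, truth in self.per_patient.items() for cid in truth.planted
        }

    def expected_events(self) -> set[tuple[str, str]]:
        return {
            (pid, cid) for pid, truth in self.per_patient.items() for cid in truth.expected
        }

    def to_json(self, path: str | Path) -> None:
        payload = {pid: asdict(truth) for pid, truth in sorted(self.per_patient.items())}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLabels":
        payload = json.loads(Path(path).read_text())
        return cls(per_patient={pid: PatientTruth(**truth) for pid, truth in payload.items()})


# ---------------------------------------------------------------------------
# row builders


def _rx_stream(
    patient_id: str,
    drug_code: str,
    start: date,
    n_scripts: int,
    strength: float,
    daily_units: float,
    script_days: int = 28,
) -> list[Prescription]:
    """Contiguous repeat stream: one script every ``script_days`` days."""
    return [
        Prescription(
            patient_id=patient_id,
            drug_code=drug_code,
            issue_date=start + timedelta(days=i * script_days),
            strength=strength,
            quantity=script_days * daily_units,
            daily_units=daily_units,
        )
        for i in range(n_scripts)
    ]


class CohortGenerator:
    """Stateful generator bound to one codebook and rule pack."""

    def __init__(self, config: SimConfig, codebook: Codebook | None = None, pack: RulePack | None = None):
        self.config = config
        self.codebook = codebook or load_bundled_codebook()
        self.pack = pack or load_bundled_rule_pack()
        config.validate(self.pack)
        self.engine_config = EngineConfig()

    # -- public API --------------------------------------------------------
    def generate(self) -> tuple[Cohort, TruthLabels]:
        rng = np.random.default_rng(self.config.seed)
        cohort: Cohort = {}
        truth = TruthLabels()
        for i in range(self.config.n_patients):
            record, patient_truth = self._generate_patient(f"P{i:06d}", rng)
            cohort[record.patient_id] = record
            truth.per_patient[record.patient_id] = patient_truth
        return cohort, truth

    # -- patient assembly --------------------------------------------------
    def _generate_patient(self, patient_id: str, rng: np.random.Generator) -> tuple[PatientRecord, PatientTruth]:
        window = self.config.window
        band = str(rng.choice(list(self.config.age_band_weights), p=list(self.config.age_band_weights.values())))
        low, high = AGE_RANGES[band]
        age = int(rng.integers(low, high + 1))
        sex = str(rng.choice(list(self.config.sex_weights), p=list(self.config.sex_weights.values())))
        patient = Patient(
            patient_id=patient_id,
            sex=sex,
            birth_year=window.start.year - age,
            registration_start=window.leadin_start - timedelta(days=int(rng.integers(365, 3650))),
        )
        record = PatientRecord(patient=patient)
        truth = PatientTruth()

        if self.config.true_coefficients is None:
            self._sample_conditions(record, rng)
            self._background_therapy(record, rng, n_classes=int(rng.poisson(self.config.background_intensity)))
            planted = self._plant_from_rates(record, rng)
            truth.planted = sorted(planted)
            if self.config.near_miss_rate and rng.random() < self.config.near_miss_rate and not planted:
                self._inject_near_miss(record, rng)
        else:
            self._outcome_linked(record, truth, rng)

        self._finalize_truth(record, truth)
        return record, truth

    def _finalize_truth(self, record: PatientRecord, truth: PatientTruth) -> None:
        if self.config.verify == "full":
            fired = {
                e.criterion_id
                for e in screen_record(record, self.pack, self.codebook, self.config.window, self.engine_config)
            }
        else:
            fired = self._fired_among(record, truth.planted) if truth.planted else set()
        missing = set(truth.planted) - fired
        if missing:
            raise PlantingError(
                f"{record.patient_id}: planted criteria failed verification: {sorted(missing)}"
            )
        truth.expected = sorted(fired)
        truth.any_pip = bool(truth.expected)
        record.prescriptions.sort(key=lambda p: (p.issue_date, p.drug_code))
        record.diagnoses.sort(key=lambda d: (d.event_date, d.condition_code))

    def _fired_among(self, record: PatientRecord, criterion_ids: list[str]) -> set[str]:
        window = self.config.window
        class_eras = build_drug_eras(record.prescriptions, self.codebook, self.engine_config.max_gap_days, "class")
        code_eras = build_drug_eras(record.prescriptions, self.codebook, self.engine_config.max_gap_days, "code")
        groups = {
            e.key: g for e in code_eras if (g := self.codebook.duplication_group(e.key)) is not None
        }
        fired = set()
        for cid in criterion_ids:
            criterion = self.pack.get(cid)
            if criterion.is_duplication:
                events = detect_duplication(record, code_eras, groups, criterion.min_overlap_days, window, criterion)
            else:
                events = evaluate_criterion(record, criterion, class_eras, window, self.codebook)
            if events:
                fired.add(cid)
        return fired

    # -- background --------------------------------------------------------
    def _sample_conditions(self, record: PatientRecord, rng: np.random.Generator) -> None:
        window = self.config.window
        for concept in sorted(self.config.condition_prevalences):
            if rng.random() < self.config.condition_prevalences[concept]:
                code = self._condition_code(concept, rng)
                record.diagnoses.append(
                    Diagnosis(
                        patient_id=record.patient_id,
                        condition_code=code,
                        event_date=window.start - timedelta(days=int(rng.integers(30, 1825))),
                    )
                )

    def _background_therapy(
        self, record: PatientRecord, rng: np.random.Generator, n_classes: int, min_scripts: int = 3, max_scripts: int = 6
    ) -> None:
        window = self.config.window
        n_classes = min(n_classes, len(BACKGROUND_CLASSES))
        classes = rng.choice(len(BACKGROUND_CLASSES), size=n_classes, replace=False)
        for idx in classes:
            drug_class = BACKGROUND_CLASSES[int(idx)]
            code = self.codebook.codes_in_class(drug_class)[0]
            n_scripts = int(rng.integers(min_scripts, max_scripts + 1))
            latest_start = window.days - 28 * n_scripts
            start = window.start + timedelta(days=int(rng.integers(0, max(1, latest_start))))
            ddd = self.codebook.ddd_amount(code)
            record.prescriptions.extend(
                _rx_stream(record.patient_id, code, start, n_scripts, strength=ddd, daily_units=1.0)
            )

    # -- planting ----------------------------------------------------------
    def _plant_from_rates(self, record: PatientRecord, rng: np.random.Generator) -> list[str]:
        planted: list[str] = []
        present_concepts = {
            self.codebook.resolve_concept(dx.condition_code) for dx in record.diagnoses
        }
        present_classes: set[str] = set()
        forbidden_concepts: set[str] = set()
        protected_classes: set[str] = set()
        for criterion in self.pack:
            rate = self.config.planting_rates.get(criterion.criterion_id, 0.0)
            if rate <= 0.0 or rng.random() >= rate:
                continue
            if not self._plantable(criterion, record, present_concepts, present_classes, forbidden_concepts, protected_classes):
                continue
            added_classes, added_concepts = self.plant_criterion(record, criterion, rng)
            present_classes.update(added_classes)
            present_concepts.update(added_concepts)
            forbidden_concepts.update(criterion.excluded_conditions)
            protected_classes.update(criterion.protective_co_drugs)
            planted.append(criterion.criterion_id)
        return planted

    def _plantable(
        self,
        criterion: CriterionDef,
        record: PatientRecord,
        present_concepts: set[str],
        present_classes: set[str],
        forbidden_concepts: set[str],
        protected_classes: set[str],
    ) -> bool:
        if criterion.sex_restriction and record.patient.sex != criterion.sex_restriction:
            return False
        if set(criterion.excluded_conditions) & present_concepts:
            return False
        needed = set(criterion.required_conditions[:1]) | set(criterion.required_conditions_all)
        if needed & forbidden_concepts:
            return False
        introduces = set(criterion.target_drugs[:1]) | set(criterion.co_drugs_required[:1])
        if introduces & protected_classes:
            return False
        if set(criterion.protective_co_drugs) & present_classes:
            return False
        return True

    def plant_criterion(
        self, record: PatientRecord, criterion: CriterionDef, rng: np.random.Generator
    ) -> tuple[set[str], set[str]]:
        """Emit rows realising one firing of ``criterion``; returns the drug
        classes and condition concepts introduced."""
        window = self.config.window
        added_classes: set[str] = set()
        added_concepts: set[str] = set()

        if criterion.is_duplication:
            group = ("group:statin", "group:ssri")[int(rng.integers(0, 2))]
            codes = self.codebook.codes_in_group(group)
            overlap = criterion.min_overlap_days + 7 + int(rng.integers(0, 28))
            n_scripts = math.ceil(overlap / 28)
            start = window.start + timedelta(days=int(rng.integers(0, window.days - 28 * n_scripts)))
            for code in codes[:2]:
                ddd = self.codebook.ddd_amount(code)
                record.prescriptions.extend(
                    _rx_stream(record.patient_id, code, start, n_scripts, strength=ddd, daily_units=1.0)
                )
                added_classes.add(self.codebook.resolve_class(code))
            return added_classes, added_concepts

        target_class = criterion.target_drugs[0]
        code = self.codebook.codes_in_class(target_class)[0]
        ddd = self.codebook.ddd_amount(code)

        duration_t = criterion.min_duration_days or 0
        era_days = max(duration_t + 7 + int(rng.integers(0, 28)), 28)
        n_scripts = math.ceil(era_days / 28)
        latest = window.days - 28 * n_scripts
        if latest < 1:
            raise PlantingError(f"{criterion.criterion_id}: era does not fit the window")
        era_start = window.start + timedelta(days=int(rng.integers(0, latest)))

        strength, daily_units = ddd, 1.0
        if criterion.dose is not None:
            factor = 1.0 if criterion.dose.comparator == "ge" else 1.25 + 0.5 * rng.random()
            if criterion.dose.units == "ddd_per_day":
                daily_units = criterion.dose.threshold * factor
            else:  # mass_per_day, strength expressed in the class's unit
                daily_units = criterion.dose.threshold * factor / ddd * 2.0
                strength = ddd / 2.0
        record.prescriptions.extend(
            _rx_stream(record.patient_id, code, era_start, n_scripts, strength=strength, daily_units=daily_units)
        )
        added_classes.add(target_class)

        for co_classes in ([criterion.co_drugs_required] if criterion.co_drugs_required else []):
            co_class = co_classes[0]
            co_code = self.codebook.codes_in_class(co_class)[0]
            co_ddd = self.codebook.ddd_amount(co_code)
            record.prescriptions.extend(
                _rx_stream(record.patient_id, co_code, era_start, max(1, n_scripts), strength=co_ddd, daily_units=1.0)
            )
            added_classes.add(co_class)

        trigger_anchor = era_start + timedelta(days=duration_t)
        concepts = list(criterion.required_conditions[:1]) + list(criterion.required_conditions_all)
        for concept in concepts:
            if criterion.condition_window_days is not None:
                offset = int(rng.integers(0, min(criterion.condition_window_days - 20, 60) + 1))
                event_date = trigger_anchor - timedelta(days=offset)
            else:
                event_date = window.start - timedelta(days=int(rng.integers(60, 720)))
            record.diagnoses.append(
                Diagnosis(
                    patient_id=record.patient_id,
                    condition_code=self._condition_code(concept, rng),
                    event_date=event_date,
                )
            )
            added_concepts.add(concept)
        return added_classes, added_concepts

    def _condition_code(self, concept: str, rng: np.random.Generator) -> str:
        codes = self.codebook.codes_for_concept(concept)
        if not codes:
            raise PlantingError(f"no condition code for concept {concept!r}")
        return codes[0]

    # -- near misses -------------------------------------------------------
    def _inject_near_miss(self, record: PatientRecord, rng: np.random.Generator) -> None:
        """Just-below-threshold exposure that must not fire any rule."""
        window = self.config.window
        kind = int(rng.integers(0, 3))
        has_fall = any(
            self.codebook.resolve_concept(dx.condition_code) == "cond:fall" for dx in record.diagnoses
        )
        if kind == 1 and has_fall:
            kind = 0  # a benzodiazepine stream would legitimately fire a falls rule
        if kind == 0:
            # duplication overlap one week short of the floor
            codes = self.codebook.codes_in_group("group:statin")[:2]
            start = window.start + timedelta(days=int(rng.integers(0, window.days - 90)))
            ddd0 = self.codebook.ddd_amount(codes[0])
            ddd1 = self.codebook.ddd_amount(codes[1])
            record.prescriptions.extend(
                _rx_stream(record.patient_id, codes[0], start, 1, strength=ddd0, daily_units=1.0, script_days=21)
            )
            record.prescriptions.extend(
                _rx_stream(record.patient_id, codes[1], start, 1, strength=ddd1, daily_units=1.0, script_days=21)
            )
        elif kind == 1:
            # long-acting benzodiazepine era below the >28-day threshold
            start = window.start + timedelta(days=int(rng.integers(0, window.days - 40)))
            record.prescriptions.extend(
                _rx_stream(record.patient_id, "d_diazepam", start, 1, strength=10.0, daily_units=1.0, script_days=21)
            )
        else:
            # digoxin at exactly the strict dose threshold
            start = window.start + timedelta(days=int(rng.integers(0, window.days - 40)))
            record.prescriptions.extend(
                _rx_stream(record.patient_id, "d_digoxin", start, 1, strength=125.0, daily_units=1.0)
            )

    # -- outcome-linked mode ------------------------------------------------
    def _outcome_linked(self, record: PatientRecord, truth: PatientTruth, rng: np.random.Generator) -> None:
        window = self.config.window
        coefs = self.config.true_coefficients or DEFAULT_TRUE_COEFFICIENTS
        poly = rng.random() < self.config.polypharmacy_rate
        bands = list(self.config.charlson_band_weights)
        cci_band = str(rng.choice(bands, p=list(self.config.charlson_band_weights.values())))
        truth.polypharmacy = poly
        truth.charlson_band = cci_band

        # constructive covariates: Charlson codes hitting the intended band
        if cci_band == "1":
            if rng.random() < 0.5:
                self._add_condition(record, "cond:liver_disease_mild", rng)
        elif cci_band == "2":
            self._add_condition(record, "cond:renal_failure", rng)
        else:
            self._add_condition(record, "cond:liver_disease_severe", rng)

        # repeat-medication streams: >=4 repeat classes iff polypharmacy,
        # capped at 2 otherwise so a planted criterion cannot flip the flag
        n_bg = int(rng.integers(4, 7)) if poly else int(rng.integers(0, 3))
        self._background_therapy(record, rng, n_classes=n_bg, min_scripts=4, max_scripts=6)

        eta = coefs.get("const", 0.0)
        if poly:
            eta += coefs.get("polypharmacy[ever]", 0.0)
        band = age_band(record.patient.birth_year, window)
        eta += coefs.get(f"age_band[{band}]", 0.0)
        eta += coefs.get(f"sex[{record.patient.sex}]", 0.0)
        eta += coefs.get(f"charlson_band[{cci_band}]", 0.0)
        p_pip = 1.0 / (1.0 + math.exp(-eta))
        if rng.random() < p_pip:
            plantable = [cid for cid in OUTCOME_PLANTABLE if cid in set(self.pack.ids)]
            criterion = self.pack.get(plantable[int(rng.integers(0, len(plantable)))])
            self.plant_criterion(record, criterion, rng)
            truth.planted = [criterion.criterion_id]

    def _add_condition(self, record: PatientRecord, concept: str, rng: np.random.Generator) -> None:
        record.diagnoses.append(
            Diagnosis(
                patient_id=record.patient_id,
                condition_code=self._condition_code(concept, rng),
                event_date=self.config.window.start - timedelta(days=int(rng.integers(60, 1825))),
            )
        )


def generate_cohort(
    config: SimConfig, codebook: Codebook | None = None, pack: RulePack | None = None
) -> tuple[Cohort, TruthLabels]:
    """Deterministic cohort + truth labels for a seeded configuration."""
    return CohortGenerator(config, codebook, pack).generate()


def write_synthetic(cohort: Cohort, truth: TruthLabels, out_dir: str | Path) -> dict[str, Path]:
    """Write the three cohort tables plus truth_labels.json."""
    paths = write_cohort(cohort, out_dir)
    truth_path = Path(out_dir) / "truth_labels.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
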