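"""Declarative STOPP criterion schema and rule-pack loading.

A criterion is a conjunction of predicates evaluated per patient per
calendar day: exposure to any target drug class, presence/absence of coded
conditions, concurrent co-prescriptions, cumulative exposure duration and
average daily dose. The bundled comprehensive pack (``stopp52``) encodes the
prescribing indicators applied to the 2007 primary-care cohort; the
truncated pack (``stopp28``) is the same file filtered by the ``subset28``
flag, mirroring the criterion subset applicable to prescription-claims data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .codebook import Codebook

DOSE_UNITS = ("ddd_per_day", "mass_per_day")
DOSE_COMPARATORS = ("gt", "ge")


class RulePackError(ValueError):
    """Rule pack fails schema or codebook-closure validation."""


@dataclass(frozen=True)
class DoseRule:
    threshold: float
    units: str = "ddd_per_day"
    comparator: str = "gt"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise RulePackError("dose threshold must be > 0")
        if self.units not in DOSE_UNITS:
            raise RulePackError(f"dose units must be one of {DOSE_UNITS}")
        if self.comparator not in DOSE_COMPARATORS:
            raise RulePackError(f"dose comparator must be one of {DOSE_COMPARATORS}")

    def passes(self, value: float) -> bool:
        return value > self.threshold if self.comparator == "gt" else value >= self.threshold


@dataclass(frozen=True)
class CriterionDef:
    criterion_id: str
    system: str
    description: str
    subset28: bool = False
    target_drugs: tuple[str, ...] = ()
    required_conditions: tuple[str, ...] = ()       # ANY of these concepts
    required_conditions_all: tuple[str, ...] = ()   # ALL of these concepts
    condition_window_days: int | None = None        # recency window for required conditions
    excluded_conditions: tuple[str, ...] = ()
    co_drugs_required: tuple[str, ...] = ()         # concurrent exposure to ANY
    protective_co_drugs: tuple[str, ...] = ()       # concurrent exposure suppresses
    min_duration_days: int | None = None            # fires strictly above
    dose: DoseRule | None = None
    sex_restriction: str | None = None
    is_duplication: bool = False
    min_overlap_days: int = 28                      # duplication rules only

    def __post_init__(self) -> None:
        if not self.target_drugs and not self.is_duplication:
            raise RulePackError(f"{self.criterion_id}: needs target_drugs or duplication")
        if self.min_duration_days is not None and self.min_duration_days <= 0:
            raise RulePackError(f"{self.criterion_id}: min_duration_days must be > 0")
        if self.condition_window_days is not None and self.condition_window_days <= 0:
            raise RulePackError(f"{self.criterion_id}: condition_window_days must be > 0")
        if self.is_duplication and self.min_overlap_days < 1:
            raise RulePackError(f"{self.criterion_id}: min_overlap_days must be >= 1")
        if self.sex_restriction is not None and self.sex_restriction not in ("male", "female"):
            raise RulePackError(f"{self.criterion_id}: sex_restriction must be male or female")


@dataclass(frozen=True)
class RulePack:
    version: str
    criteria: tuple[CriterionDef, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    def get(self, criterion_id: str) -> CriterionDef:
        for criterion in self.criteria:
            if criterion.criterion_id == criterion_id:
                return criterion
        raise KeyError(criterion_id)

    @property
    def ids(self) -> list[str]:
        return [c.criterion_id for c in self.criteria]

    def subset(self) -> "RulePack":
        """The truncated pack: criteria flagged ``subset28``."""
        return RulePack(
            version=self.version + "-subset28",
            criteria=tuple(c for c in self.criteria if c.subset28),
        )


def _criterion_from_mapping(raw: dict) -> CriterionDef:
    dose = None
    if "dose" in raw and raw["dose"] is not None:
        dose = DoseRule(**raw["dose"])
    return CriterionDef(
        criterion_id=str(raw["id"]),
        system=str(raw.get("system", "unspecified")),
        description=str(raw.get("description", "")),
        subset28=bool(raw.get("subset28", False)),
        target_drugs=tuple(raw.get("target_drugs", ()) or ()),
        required_conditions=tuple(raw.get("required_conditions", ()) or ()),
        required_conditions_all=tuple(raw.get("required_conditions_all", ()) or ()),
        condition_window_days=raw.get("condition_window_days"),
        excluded_conditions=tuple(raw.get("excluded_conditions", ()) or ()),
        co_drugs_required=tuple(raw.get("co_drugs_required", ()) or ()),
        protective_co_drugs=tuple(raw.get("protective_co_drugs", ()) or ()),
        min_duration_days=raw.get("min_duration_days"),
        dose=dose,
        sex_restriction=raw.get("sex_restriction"),
        is_duplication=bool(raw.get("duplication", False)),
        min_overlap_days=int(raw.get("min_overlap_days", 28)),
    )


def load_rule_pack(path: str | Path) -> RulePack:
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "criteria" not in raw:
        raise RulePackError(f"{path}: expected mapping with a 'criteria' list")
    criteria = []
    seen: set[str] = set()
    for entry in raw["criteria"]:
        criterion = _criterion_from_mapping(entry)
        if criterion.criterion_id in seen:
            raise RulePackError(f"duplicate criterion id {criterion.criterion_id!r}")
        seen.add(criterion.criterion_id)
        criteria.append(criterion)
    return RulePack(version=str(raw.get("version", "unversioned")), criteria=tuple(criteria))


def bundled_rule_pack_path() -> Path:
    return Path(str(resources.files("pipscreen").joinpath("data/stopp52.yaml")))


def load_bundled_rule_pack(subset: bool = False) -> RulePack:
    """The shipped comprehensive pack, or its ``subset28`` view."""
    pack = load_rule_pack(bundled_rule_pack_path())
    return pack.subset() if subset else pack


def validate_against_codebook(pack: RulePack, codebook: Codebook) -> None:
    """Closure check: every token a criterion references resolves in the codebook."""
    classes = codebook.drug_classes
    concepts = codebook.concepts
    problems: list[str] = []
    for criterion in pack:
        for token in (*criterion.target_drugs, *criterion.co_drugs_required, *criterion.protective_co_drugs):
            if token not in classes:
                problems.append(f"{criterion.criterion_id}: drug class {token!r} not in codebook")
        for token in (
            *criterion.required_conditions,
            *criterion.required_conditions_all,
            *criterion.excluded_conditions,
        ):
            if token not in concepts:
                problems.append(f"{criterion.criterion_id}: condition concept {token!r} not in codebook")
        if criterion.is_duplication and not codebook.duplication_groups:
            problems.append(f"{criterion.criterion_id}: codebook defines no duplication groups")
    if problems:
        raise RulePackError("rule pack does not close over codebook:\n" + "\n".join(problems))
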