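"""Synthetic drug and condition vocabularies.

Real UK primary-care records code drugs with Multilex and diagnoses with Read
codes, and dose rules are normalised through the WHO defined-daily-dose (DDD)
index; none of those dictionaries can be redistributed here. The bundled
codebook is a self-consistent synthetic stand-in: each drug code maps to
exactly one drug class, optionally to a therapeutic-duplication group, and to
a DDD amount (mass defining one DDD per day, in the class's strength unit);
each condition code maps to a condition concept and, where applicable, to one
of the 17 classic Charlson comorbidity categories with its weight (1, 2, 3
or 6). The schema accepts user-supplied real vocabularies with the same
columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

#: Marker returned for codes absent from the codebook.
UNKNOWN = "unknown"

CHARLSON_WEIGHTS = {1, 2, 3, 6}


class CodebookError(ValueError):
    """Codebook fails validation (duplicate keys, bad DDD, bad weight)."""


@dataclass(frozen=True)
class DrugEntry:
    drug_code: str
    drug_class: str
    ddd_amount: float
    duplication_group: str | None = None
    route: str = "oral"
    strength_unit: str = "mg"

    def __post_init__(self) -> None:
        if self.ddd_amount <= 0:
            raise CodebookError(f"{self.drug_code}: ddd_amount must be > 0")


@dataclass(frozen=True)
class ConditionEntry:
    condition_code: str
    concept: str
    charlson_category: str | None = None
    charlson_weight: int | None = None

    def __post_init__(self) -> None:
        if (self.charlson_category is None) != (self.charlson_weight is None):
            raise CodebookError(
                f"{self.condition_code}: charlson_weight present iff charlson_category present"
            )
        if self.charlson_weight is not None and self.charlson_weight not in CHARLSON_WEIGHTS:
            raise CodebookError(
                f"{self.condition_code}: charlson_weight must be in {sorted(CHARLSON_WEIGHTS)}"
            )


class Codebook:
    """Validated drug and condition lookups."""

    def __init__(self, drugs: list[DrugEntry], conditions: list[ConditionEntry], version: str = "unversioned"):
        self.version = version
        self.drugs: dict[str, DrugEntry] = {}
        for entry in drugs:
            if entry.drug_code in self.drugs:
                raise CodebookError(f"duplicate drug_code {entry.drug_code!r}")
            self.drugs[entry.drug_code] = entry
        self.conditions: dict[str, ConditionEntry] = {}
        for entry in conditions:
            if entry.condition_code in self.conditions:
                raise CodebookError(f"duplicate condition_code {entry.condition_code!r}")
            self.conditions[entry.condition_code] = entry
        self._warned: set[str] = set()

    # -- drug side ---------------------------------------------------------
    def resolve_class(self, drug_code: str) -> str:
        """Drug class for a code; :data:`UNKNOWN` (logged once) if absent."""
        entry = self.drugs.get(drug_code)
        if entry is None:
            if drug_code not in self._warned:
                self._warned.add(drug_code)
                log.warning("unknown drug code %r", drug_code)
            return UNKNOWN
        return entry.drug_class

    def duplication_group(self, drug_code: str) -> str | None:
        entry = self.drugs.get(drug_code)
        return entry.duplication_group if entry else None

    def ddd_amount(self, drug_code: str) -> float | None:
        entry = self.drugs.get(drug_code)
        return entry.ddd_amount if entry else None

    def codes_in_class(self, drug_class: str) -> list[str]:
        return sorted(c for c, e in self.drugs.items() if e.drug_class == drug_class)

    def codes_in_group(self, group: str) -> list[str]:
        return sorted(c for c, e in self.drugs.items() if e.duplication_group == group)

    @property
    def drug_classes(self) -> set[str]:
        return {e.drug_class for e in self.drugs.values()}

    @property
    def duplication_groups(self) -> set[str]:
        return {e.duplication_group for e in self.drugs.values() if e.duplication_group}

    # -- condition side ----------------------------------------------------
    def resolve_concept(self, condition_code: str) -> str:
        entry = self.conditions.get(condition_code)
        if entry is None:
            if condition_code not in self._warned:
                self._warned.add(condition_code)
                log.warning("unknown condition code %r", condition_code)
            return UNKNOWN
        return entry.concept

    def charlson(self, condition_code: str) -> tuple[str, int] | None:
        entry = self.conditions.get(condition_code)
        if entry is None or entry.charlson_category is None:
            return None
        return entry.charlson_category, entry.charlson_weight  # type: ignore[return-value]

    def codes_for_concept(self, concept: str) -> list[str]:
        return sorted(c for c, e in self.conditions.items() if e.concept == concept)

    @property
    def concepts(self) -> set[str]:
        return {e.concept for e in self.conditions.values()}


def load_codebook(path: str | Path) -> Codebook:
    """Load and validate a YAML codebook; duplicate keys are a hard error."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "drugs" not in raw or "conditions" not in raw:
        raise CodebookError(f"{path}: expected mapping with 'drugs' and 'conditions'")
    drugs = [DrugEntry(**row) for row in raw["drugs"]]
    conditions = [ConditionEntry(**row) for row in raw["conditions"]]
    return Codebook(drugs, conditions, version=str(raw.get("version", "unversioned")))


def bundled_codebook_path() -> Path:
    return Path(str(resources.files("pipscreen").joinpath("data/codebook.yaml")))


def load_bundled_codebook() -> Codebook:
    """The synthetic vocabulary shipped with the package."""
    return load_codebook(bundled_codebook_path())
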