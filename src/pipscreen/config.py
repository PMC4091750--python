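"""Run configuration: YAML-backed settings for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from .codebook import Codebook, load_bundled_codebook, load_codebook
from .engine import EngineConfig
from .model import StudyWindow
from .rules import RulePack, load_bundled_rule_pack, load_rule_pack

DEFAULT_WINDOW = StudyWindow(start=date(2007, 1, 1), end=date(2008, 1, 1), leadin_days=90)


class ConfigError(ValueError):
    """Run configuration is invalid or references missing files."""


@dataclass
class RunConfig:
    patient_path: Path | None = None
    therapy_path: Path | None = None
    clinical_path: Path | None = None
    codebook_path: str = "bundled"
    rule_pack: str = "stopp52"          # stopp52 | stopp28 | path to a YAML file
    window: StudyWindow = DEFAULT_WINDOW
    engine: EngineConfig = field(default_factory=EngineConfig)
    ci_method: str = "wilson"
    continuity_correction: bool = True
    out_dir: Path = Path("out")
    seed: int = 0
    n_patients: int = 500
    near_miss_rate: float = 0.0

    def validate_inputs(self) -> None:
        for name, path in (
            ("patient", self.patient_path),
            ("therapy", self.therapy_path),
            ("clinical", self.clinical_path),
        ):
            if path is None:
                raise ConfigError(f"missing input path for the {name} table")
            if not Path(path).exists():
                raise ConfigError(f"{name} table not found: {path}")
        if self.codebook_path != "bundled" and not Path(self.codebook_path).exists():
            raise ConfigError(f"codebook not found: {self.codebook_path}")
        if self.rule_pack not in ("stopp52", "stopp28") and not Path(self.rule_pack).exists():
            raise ConfigError(f"rule pack not found: {self.rule_pack}")
        if self.ci_method not in ("wilson", "wald"):
            raise ConfigError("ci_method must be wilson or wald")
        if self.engine.max_gap_days < 0:
            raise ConfigError("max_gap_days must be >= 0")

    def load_codebook(self) -> Codebook:
        if self.codebook_path == "bundled":
            return load_bundled_codebook()
        return load_codebook(self.codebook_path)

    def load_rule_pack(self) -> RulePack:
        if self.rule_pack == "stopp52":
            return load_bundled_rule_pack()
        if self.rule_pack == "stopp28":
            return load_bundled_rule_pack(subset=True)
        return load_rule_pack(self.rule_pack)


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    config = RunConfig()
    inputs = raw.get("inputs", {})
    if "patient" in inputs:
        config.patient_path = Path(inputs["patient"])
    if "therapy" in inputs:
        config.therapy_path = Path(inputs["therapy"])
    if "clinical" in inputs:
        config.clinical_path = Path(inputs["clinical"])
    config.codebook_path = str(raw.get("codebook", "bundled"))
    config.rule_pack = str(raw.get("rule_pack", "stopp52"))
    if "window" in raw:
        w = raw["window"]
        config.window = StudyWindow(
            start=_parse_date(w["start"]),
            end=_parse_date(w["end"]),
            leadin_days=int(w.get("leadin_days", 90)),
        )
    if "engine" in raw:
        e = raw["engine"]
        config.engine = EngineConfig(
            max_gap_days=int(e.get("max_gap_days", 30)),
            duplication_min_overlap_days=e.get("duplication_min_overlap_days"),
        )
    stats = raw.get("stats", {})
    config.ci_method = str(stats.get("ci_method", "wilson"))
    config.continuity_correction = bool(stats.get("continuity_correction", True))
    config.out_dir = Path(raw.get("out_dir", "out"))
    sim = raw.get("simulate", {})
    config.seed = int(sim.get("seed", raw.get("seed", 0)))
    config.n_patients = int(sim.get("n_patients", 500))
    config.near_miss_rate = float(sim.get("near_miss_rate", 0.0))
    return config
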