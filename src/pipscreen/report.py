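"""Assembly of the three study-shaped result tables plus a JSON summary.

* cohort characteristics by PIP status (sex, age band, Charlson band,
  polypharmacy), counts with row percentages;
* per-criterion prevalence (n, %, 95% CI) over the screened cohort;
* association table: unadjusted 2x2 odds ratios per covariate level against
  its reference, and adjusted odds ratios from the multivariable logistic
  model.

Every number in the tables is re-derivable from the event table and the
covariate table alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .codebook import Codebook
from .covariates import AGE_BANDS, CHARLSON_BANDS, derive_covariates
from .engine import EngineConfig, ScreenResult, screen_cohort
from .model import Cohort, StudyWindow
from .rules import RulePack
from .stats import (
    SeparationError,
    Table2x2,
    fit_logistic,
    odds_ratio,
    pip_count_distribution,
    prevalence_with_ci,
)

log = logging.getLogger(__name__)

REGRESSION_LEVELS: dict[str, list[str]] = {
    "polypharmacy": ["never", "ever"],
    "age_band": list(AGE_BANDS),
    "sex": ["male", "female", "missing"],
    "charlson_band": list(CHARLSON_BANDS),
}


def events_frame(result: ScreenResult) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "criterion_id": e.criterion_id,
            "first_trigger_date": e.first_trigger_date.isoformat(),
        }
        for e in sorted(result.events, key=lambda e: (e.patient_id, e.criterion_id))
    ]
    return pd.DataFrame(rows, columns=["patient_id", "criterion_id", "first_trigger_date"])


def evidence_log(result: ScreenResult) -> list[dict]:
    return [
        {
            "patient_id": e.patient_id,
            "criterion_id": e.criterion_id,
            "first_trigger_date": e.first_trigger_date.isoformat(),
            "evidence": list(e.evidence),
        }
        for e in sorted(result.events, key=lambda e: (e.patient_id, e.criterion_id))
    ]


def characteristics_table(covariates: pd.DataFrame, pip_positive: set[str]) -> pd.DataFrame:
    """Cohort characteristics split by any-PIP status with row percentages."""
    cov = covariates.copy()
    cov["pip"] = cov["patient_id"].isin(pip_positive)
    cov["polypharmacy_level"] = cov["polypharmacy"].map({False: "never", True: "ever"})
    rows = []
    for variable, column, levels in (
        ("sex", "sex", ["male", "female", "missing"]),
        ("age_band", "age_band", list(AGE_BANDS)),
        ("charlson_band", "charlson_band", list(CHARLSON_BANDS)),
        ("polypharmacy", "polypharmacy_level", ["never", "ever"]),
    ):
        for level in levels:
            sub = cov[cov[column] == level]
            n = len(sub)
            n_pip = int(sub["pip"].sum())
            rows.append(
                {
                    "variable": variable,
                    "level": level,
                    "n_pip": n_pip,
                    "pct_pip": round(100.0 * n_pip / n, 1) if n else 0.0,
                    "n_no_pip": n - n_pip,
                    "pct_no_pip": round(100.0 * (n - n_pip) / n, 1) if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def per_criterion_table(result: ScreenResult, pack: RulePack, ci_method: str = "wilson") -> pd.DataFrame:
    counts = result.count_per_criterion()
    rows = []
    for criterion in pack:
        n = counts.get(criterion.criterion_id, 0)
        est = prevalence_with_ci(n, result.n_patients, method=ci_method) if result.n_patients else None
        pct, low, high = est.rounded() if est else (0.0, 0.0, 0.0)
        rows.append(
            {
                "criterion_id": criterion.criterion_id,
                "system": criterion.system,
                "description": criterion.description,
                "n": n,
                "pct": pct,
                "ci_low_pct": low,
                "ci_high_pct": high,
            }
        )
    return pd.DataFrame(rows)


def association_table(
    covariates: pd.DataFrame, pip_positive: set[str], continuity_correction: bool = True
) -> pd.DataFrame:
    """Unadjusted and adjusted ORs for each non-reference covariate level."""
    cov = covariates.copy()
    cov["pip"] = cov["patient_id"].isin(pip_positive)
    cov["polypharmacy"] = cov["polypharmacy"].map({False: "never", True: "ever"})

    adjusted: dict[str, tuple[float, float, float]] = {}
    try:
        fits = fit_logistic(cov["pip"].astype(float), cov, REGRESSION_LEVELS)
        adjusted = {f.term: (f.odds_ratio, f.ci_low, f.ci_high) for f in fits}
    except (SeparationError, ValueError) as exc:
        log.warning("adjusted model not estimable: %s", exc)

    rows = []
    for column, levels in REGRESSION_LEVELS.items():
        reference = levels[0]
        ref_sub = cov[cov[column] == reference]
        rows.append(
            {"variable": column, "level": f"{reference} (ref)", "or_unadjusted": 1.0,
             "ci_low": None, "ci_high": None, "or_adjusted": 1.0, "aci_low": None, "aci_high": None}
        )
        for level in levels[1:]:
            sub = cov[cov[column] == level]
            table = Table2x2(
                a=int(sub["pip"].sum()),
                b=int((~sub["pip"]).sum()),
                c=int(ref_sub["pip"].sum()),
                d=int((~ref_sub["pip"]).sum()),
            )
            try:
                est = odds_ratio(table, term=f"{column}[{level}]", correction=continuity_correction)
                unadj = (round(est.odds_ratio, 2), round(est.ci_low, 2), round(est.ci_high, 2))
            except ValueError:
                unadj = (None, None, None)
            adj = adjusted.get(f"{column}[{level}]")
            rows.append(
                {
                    "variable": column,
                    "level": level,
                    "or_unadjusted": unadj[0],
                    "ci_low": unadj[1],
                    "ci_high": unadj[2],
                    "or_adjusted": round(adj[0], 2) if adj else None,
                    "aci_low": round(adj[1], 2) if adj else None,
                    "aci_high": round(adj[2], 2) if adj else None,
                }
            )
    return pd.DataFrame(rows)


def build_report(
    cohort: Cohort,
    pack: RulePack,
    codebook: Codebook,
    window: StudyWindow,
    engine_config: EngineConfig = EngineConfig(),
    ci_method: str = "wilson",
    continuity_correction: bool = True,
) -> dict:
    """Screen, derive covariates and assemble all outputs in memory."""
    result = screen_cohort(cohort, pack, codebook, window, engine_config)
    covariates = derive_covariates(cohort, codebook, window)
    positive = result.patients_with_any()
    n = len(cohort)

    overall = prevalence_with_ci(len(positive), n, method=ci_method) if n else None
    by_patient = {pid: result.criteria_fired(pid) for pid in positive}
    distribution = pip_count_distribution(by_patient, n)

    summary = {
        "n_patients": n,
        "rule_pack": pack.version,
        "n_criteria": len(pack),
        "n_pip_patients": len(positive),
        "prevalence_pct": round(overall.pct, 1) if overall else 0.0,
        "prevalence_ci_pct": [round(100 * overall.ci_low, 1), round(100 * overall.ci_high, 1)] if overall else [0.0, 0.0],
        "pip_count_distribution": distribution,
    }
    return {
        "events": events_frame(result),
        "evidence": evidence_log(result),
        "covariates": covariates,
        "characteristics": characteristics_table(covariates, positive),
        "per_criterion": per_criterion_table(result, pack, ci_method),
        "associations": association_table(covariates, positive, continuity_correction),
        "summary": summary,
        "screen_result": result,
    }


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "evidence": out / "evidence.json",
        "covariates": out / "covariates.csv",
        "characteristics": out / "table_characteristics.csv",
        "per_criterion": out / "table_per_criterion.csv",
        "associations": out / "table_associations.csv",
        "summary": out / "summary.json",
    }
    report["events"].to_csv(paths["events"], index=False)
    paths["evidence"].write_text(json.dumps(report["evidence"], indent=1))
    report["covariates"].to_csv(paths["covariates"], index=False)
    report["characteristics"].to_csv(paths["characteristics"], index=False)
    report["per_criterion"].to_csv(paths["per_criterion"], index=False)
    report["associations"].to_csv(paths["associations"], index=False)
    paths["summary"].write_text(json.dumps(report["summary"], indent=1, sort_keys=True))
    return paths
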