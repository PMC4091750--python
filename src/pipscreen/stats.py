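"""Prevalence, 2x2 odds ratios and multivariable logistic regression.

Binomial confidence intervals default to the Wilson score interval (well
behaved at small n; Wald is available and matches large-sample results).
2x2 odds ratios use the cross-product estimate with a Woolf (log-scale)
95% CI, optionally with the Haldane-Anscombe 0.5 continuity correction for
zero cells. The multivariable model is a binomial GLM (logit link) fitted by
iteratively reweighted least squares via statsmodels; categorical covariates
enter with declared reference levels and coefficients are reported as
odds ratios with Wald 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint


class SeparationError(RuntimeError):
    """The likelihood is degenerate (separation or constant outcome).

    Coefficients diverge and Wald intervals are meaningless; a penalised
    (e.g. Firth) fit or collapsing sparse categories is advised.
    """


@dataclass(frozen=True)
class PrevalenceEstimate:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    method: str

    @property
    def pct(self) -> float:
        return 100.0 * self.proportion

    def rounded(self, digits: int = 1) -> tuple[float, float, float]:
        """(%, CI low %, CI high %) at table rounding."""
        return (
            round(self.pct, digits),
            round(100.0 * self.ci_low, digits),
            round(100.0 * self.ci_high, digits),
        )


@dataclass(frozen=True)
class OREstimate:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    adjusted: bool
    p_value: float | None = None


@dataclass(frozen=True)
class Table2x2:
    """Counts: a = exposed with outcome, b = exposed without,
    c = unexposed with outcome, d = unexposed without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")


def prevalence_with_ci(numerator: int, denominator: int, method: str = "wilson") -> PrevalenceEstimate:
    """Proportion with a 95% CI (Wilson score by default, Wald optional)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    if method not in ("wilson", "wald"):
        raise ValueError("method must be 'wilson' or 'wald'")
    sm_method = "wilson" if method == "wilson" else "normal"
    low, high = proportion_confint(numerator, denominator, alpha=0.05, method=sm_method)
    return PrevalenceEstimate(
        numerator=numerator,
        denominator=denominator,
        proportion=numerator / denominator,
        ci_low=float(max(0.0, low)),
        ci_high=float(min(1.0, high)),
        method=method,
    )


def odds_ratio(table: Table2x2, term: str = "exposure", correction: bool = False) -> OREstimate:
    """Cross-product OR with Woolf 95% CI; 0.5 correction behind a flag."""
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0:
        if not correction:
            raise ValueError("zero cell; enable the Haldane-Anscombe correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    z = 1.959963984540054
    return OREstimate(
        term=term,
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        adjusted=False,
        p_value=2 * _norm_sf(abs(log_or / se)),
    )


def _norm_sf(z: float) -> float:
    return float(norm.sf(z))


def _design_matrix(
    covariate_rows: pd.DataFrame,
    covariates: dict[str, list[str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-coded design with declared reference levels (first in each list)."""
    pieces = []
    names: list[str] = []
    for col, levels in covariates.items():
        series = covariate_rows[col]
        if series.dtype == bool:
            series = series.map({False: levels[0], True: levels[1]})
        observed = set(series.unique())
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"{col}: unexpected level(s) {sorted(unknown)}")
        for level in levels[1:]:
            if level not in observed:
                continue  # absent level contributes no column
            name = f"{col}[{level}]"
            pieces.append((series == level).astype(float).rename(name))
            names.append(name)
    design = pd.concat(pieces, axis=1)
    design.insert(0, "const", 1.0)
    return design, names


def fit_logistic(
    outcome: pd.Series,
    covariate_rows: pd.DataFrame,
    covariates: dict[str, list[str]],
    tol: float = 1e-8,
    maxiter: int = 100,
) -> list[OREstimate]:
    """Adjusted ORs from a logit GLM.

    ``covariates`` maps column name to its ordered levels, reference first
    (e.g. ``{"polypharmacy": ["never", "ever"], "age_band": ["70-74", ...]}``).
    Boolean columns are mapped onto their two declared levels.
    Raises :class:`SeparationError` on constant outcomes or detected
    separation and ValueError on a rank-deficient design.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise SeparationError("outcome is constant; model is degenerate")
    design, names = _design_matrix(covariate_rows, covariates)
    x = design.to_numpy()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise SeparationError(f"logistic fit failed: {exc}; consider penalization") from exc
    if not np.all(np.isfinite(fit.bse)) or np.max(np.abs(fit.params)) > 30 or np.max(fit.bse) > 50:
        raise SeparationError("diverging coefficients suggest separation; consider penalization")
    conf = fit.conf_int()
    out = []
    for name in names:
        out.append(
            OREstimate(
                term=name,
                odds_ratio=float(np.exp(fit.params[name])),
                ci_low=float(np.exp(conf.loc[name, 0])),
                ci_high=float(np.exp(conf.loc[name, 1])),
                adjusted=True,
                p_value=float(fit.pvalues[name]),
            )
        )
    return out


def pip_count_distribution(events_by_patient: dict[str, set[str]], n_cohort: int) -> dict[str, int]:
    """Patients with exactly 1, exactly 2, and >= 3 distinct criteria fired.

    ``events_by_patient`` maps patient id to the set of distinct criteria
    fired; patients with none may be absent. The three bins partition the
    PIP-positive population; "0" completes the partition of the cohort.
    """
    bins = {"0": 0, "1": 0, "2": 0, "3+": 0}
    positives = 0
    for criteria in events_by_patient.values():
        k = len(criteria)
        if k == 0:
            continue
        positives += 1
        bins["1" if k == 1 else "2" if k == 2 else "3+"] += 1
    bins["0"] = n_cohort - positives
    return bins
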