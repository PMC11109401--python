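"""Screening-performance metrics and risk-factor analysis.

Sensitivity surrogate: the positive-trigger rate γ, the percent of
admissions with at least one fired trigger.  Specificity surrogates: the
positive predictive value (ADEs identified by a trigger / positive
triggers, per trigger and overall) and three detection-rate measures —
percent of admissions with an ADE, ADEs per 100 admissions, ADEs per
1,000 patient-days — with 95% confidence intervals.

Two CI constructions are provided and documented; neither is claimed to
match any externally printed interval, whose method is typically
unstated: ``normal`` uses the normal approximation on per-admission event
counts (point ± 1.96·SD/√N, scaled to the denominator), ``poisson`` uses
point ± 1.96·√(count), scaled.

Risk-factor screens follow the conventional two-stage recipe: univariate
χ²/t tests, then a maximum-likelihood logistic model on the variables
passing the screen, reporting odds ratios with Wald 95% CIs.
"""

from __future__ import annotations

import math
import warnings
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import stats

import statsmodels.api as sm

from .adjudication import ADERecord
from .cohort import AdmissionRecord, Cohort
from .triggers import TRIGGER_ORDER, TriggerDefinition, TriggerHit, builtin_registry


class UndefinedMetricError(ValueError):
    """A rate was requested over an empty denominator."""


class RateWithCI(BaseModel):
    rate: float
    ci_low: float
    ci_high: float
    method: str


class PPVRow(BaseModel):
    trigger_id: str
    positives: int
    linked_ades: int
    ppv: float          # percent; 0.0 when undefined (see flag)
    undefined: bool = False


class CohortMetrics(BaseModel):
    n_admissions: int
    total_patient_days: int
    gamma: float                     # percent of admissions with >=1 hit
    per_trigger: list[PPVRow]
    overall_ppv: float
    n_positive_triggers: int         # triggers with >=1 positive
    n_linked_triggers: int           # triggers with >=1 linked ADE
    total_hits: int
    total_linked_ades: int           # sum of per-trigger linked counts
    n_unique_ades: int
    pct_admissions_with_ade: float
    ades_per_100_admissions: RateWithCI
    ades_per_1000_patient_days: RateWithCI
    pct_admissions_with_sae: float
    severity_distribution: dict[str, tuple[int, float]]
    soc_distribution: dict[str, tuple[int, float]]
    drug_category_distribution: dict[str, tuple[int, float]]
    causality_distribution: dict[str, tuple[int, float]]


def positive_trigger_rate(cohort: Cohort, hits: list[TriggerHit]) -> float:
    """γ: percent of admissions with at least one positive trigger."""
    if not cohort:
        raise UndefinedMetricError("positive trigger rate undefined on empty cohort")
    positive = {h.admission_id for h in hits}
    return 100.0 * len(positive) / len(cohort)


def format_ppv(ppv: float) -> str:
    """Display convention: one decimal below 10%, integer percent otherwise."""
    return f"{ppv:.1f}" if ppv < 10 else f"{ppv:.0f}"


def ppv_table(
    hits: list[TriggerHit],
    ades: list[ADERecord],
    registry: Optional[list[TriggerDefinition]] = None,
) -> tuple[list[PPVRow], float]:
    """Per-trigger and overall positive predictive value.

    An ADE linked to k triggers contributes to k rows; the overall PPV is
    total linked counts over total positives (equivalently the
    positives-weighted mean of per-trigger PPVs).  Triggers with zero
    positives report a flagged 0.0.
    """
    if registry is None:
        registry = builtin_registry()
    hit_keys = {(h.admission_id, h.trigger_id) for h in hits}
    for ade in ades:
        for tid in ade.linked_triggers:
            if (ade.admission_id, tid) not in hit_keys:
                raise ValueError(
                    f"ADE {ade.ade_id} linked to trigger {tid} with no hit on "
                    f"admission {ade.admission_id}")
    positives: dict[str, int] = {d.trigger_id: 0 for d in registry}
    linked: dict[str, int] = {d.trigger_id: 0 for d in registry}
    for h in hits:
        positives[h.trigger_id] += 1
    for ade in ades:
        for tid in ade.linked_triggers:
            linked[tid] += 1
    rows = []
    for d in registry:
        pos, lnk = positives[d.trigger_id], linked[d.trigger_id]
        if pos == 0:
            rows.append(PPVRow(trigger_id=d.trigger_id, positives=0,
                               linked_ades=lnk, ppv=0.0, undefined=True))
        else:
            rows.append(PPVRow(trigger_id=d.trigger_id, positives=pos,
                               linked_ades=lnk, ppv=100.0 * lnk / pos))
    total_pos = sum(positives.values())
    total_lnk = sum(linked.values())
    overall = 100.0 * total_lnk / total_pos if total_pos else 0.0
    return rows, overall


def ade_rates(
    ades: list[ADERecord],
    cohort: Cohort,
    ci_method: Literal["normal", "poisson"] = "normal",
) -> dict:
    """The three detection-rate measures with 95% CIs.

    Expects unique (deduplicated, causality-filtered) ADEs.
    """
    n = len(cohort)
    if n == 0:
        raise UndefinedMetricError("rates undefined on empty cohort")
    days = sum(adm.length_of_stay for adm in cohort)
    if days == 0:
        raise UndefinedMetricError("zero patient-days")
    counts = pd.Series(0, index=[adm.admission_id for adm in cohort], dtype=float)
    for ade in ades:
        counts[ade.admission_id] += 1
    total = int(counts.sum())
    pct_with_ade = 100.0 * (counts > 0).sum() / n
    per100 = 100.0 * total / n
    per1000d = 1000.0 * total / days
    z = 1.96
    if ci_method == "normal":
        sd = float(counts.std(ddof=1)) if n > 1 else 0.0
        half = z * sd / math.sqrt(n)
        per100_ci = (per100 - 100.0 * half, per100 + 100.0 * half)
        scale = 1000.0 * n / days          # per-admission -> per-1000-days
        per1000_ci = (per1000d - scale * half, per1000d + scale * half)
    elif ci_method == "poisson":
        half = z * math.sqrt(total)
        per100_ci = (per100 - 100.0 * half / n, per100 + 100.0 * half / n)
        per1000_ci = (per1000d - 1000.0 * half / days, per1000d + 1000.0 * half / days)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {
        "pct_admissions_with_ade": pct_with_ade,
        "ades_per_100_admissions": RateWithCI(
            rate=per100, ci_low=per100_ci[0], ci_high=per100_ci[1], method=ci_method),
        "ades_per_1000_patient_days": RateWithCI(
            rate=per1000d, ci_low=per1000_ci[0], ci_high=per1000_ci[1],
            method=ci_method),
        "total_patient_days": days,
    }


def summarize_ades(ades: list[ADERecord]) -> dict[str, dict[str, tuple[int, float]]]:
    """Severity, system-organ and suspected-drug-category distributions.

    Severity and SOC percentages are over unique ADEs; the drug-category
    tally counts every suspected-drug mention, so its total may exceed the
    ADE count (one event can have several suspected drugs).
    """
    n = len(ades)
    severity: dict[str, int] = {}
    soc: dict[str, int] = {}
    causality: dict[str, int] = {}
    drugs: dict[str, int] = {}
    for ade in ades:
        severity[f"grade-{ade.ctcae_grade}"] = severity.get(f"grade-{ade.ctcae_grade}", 0) + 1
        soc[ade.system_organ_class] = soc.get(ade.system_organ_class, 0) + 1
        causality[ade.causality] = causality.get(ade.causality, 0) + 1
        for _, cls in ade.suspected_drugs:
            drugs[cls] = drugs.get(cls, 0) + 1
    total_drugs = sum(drugs.values())

    def pct(d: dict[str, int], denom: int) -> dict[str, tuple[int, float]]:
        return {k: (v, 100.0 * v / denom if denom else 0.0)
                for k, v in sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))}

    return {
        "severity": pct(severity, n),
        "soc": pct(soc, n),
        "drug_category": pct(drugs, total_drugs),
        "causality": pct(causality, n),
    }


def compute_cohort_metrics(
    cohort: Cohort,
    hits: list[TriggerHit],
    ades: list[ADERecord],
    registry: Optional[list[TriggerDefinition]] = None,
    ci_method: Literal["normal", "poisson"] = "normal",
) -> CohortMetrics:
    """Assemble the full metrics bundle from screening + adjudication output."""
    rows, overall = ppv_table(hits, ades, registry)
    rates = ade_rates(ades, cohort, ci_method)
    dists = summarize_ades(ades)
    sae_adms = {a.admission_id for a in ades if a.sae}
    return CohortMetrics(
        n_admissions=len(cohort),
        total_patient_days=rates["total_patient_days"],
        gamma=positive_trigger_rate(cohort, hits),
        per_trigger=rows,
        overall_ppv=overall,
        n_positive_triggers=sum(1 for r in rows if r.positives > 0),
        n_linked_triggers=sum(1 for r in rows if r.linked_ades > 0),
        total_hits=len(hits),
        total_linked_ades=sum(r.linked_ades for r in rows),
        n_unique_ades=len(ades),
        pct_admissions_with_ade=rates["pct_admissions_with_ade"],
        ades_per_100_admissions=rates["ades_per_100_admissions"],
        ades_per_1000_patient_days=rates["ades_per_1000_patient_days"],
        pct_admissions_with_sae=100.0 * len(sae_adms) / len(cohort),
        severity_distribution=dists["severity"],
        soc_distribution=dists["soc"],
        drug_category_distribution=dists["drug_category"],
        causality_distribution=dists["causality"],
    )


# ---------------------------------------------------------------------------
# Risk-factor analysis
# ---------------------------------------------------------------------------

#: covariates screened by default, with their test type
SCREEN_VARIABLES: dict[str, str] = {
    "age": "continuous",
    "sex": "categorical",
    "length_of_stay": "continuous",
    "n_combined_drugs": "continuous",
    "prior_chemotherapy_count": "continuous",
    "prior_adr_history": "categorical",
    "radiotherapy": "categorical",
    "tumor_stage": "categorical",
    "tumor_category": "categorical",
}


class RiskFactorResult(BaseModel):
    outcome: str
    converged: bool
    n: int
    univariate: dict[str, tuple[float, float]]       # var -> (statistic, p)
    model_terms: dict[str, tuple[float, float, float, float]]  # OR, lo, hi, p
    separation_flags: list[str] = []


def outcome_labels(cohort: Cohort, ades: list[ADERecord],
                   outcome: Literal["ADE", "SAE"]) -> pd.Series:
    flagged = {a.admission_id for a in ades if outcome == "ADE" or a.sae}
    return pd.Series([adm.admission_id in flagged for adm in cohort],
                     index=[adm.admission_id for adm in cohort], dtype=int)


def covariate_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [{
        "age": adm.age,
        "sex": adm.sex,
        "length_of_stay": adm.length_of_stay,
        "n_combined_drugs": adm.n_combined_drugs,
        "prior_chemotherapy_count": adm.prior_chemotherapy_count,
        "prior_adr_history": int(adm.prior_adr_history),
        "radiotherapy": int(adm.radiotherapy),
        "tumor_stage": adm.tumor_stage,
        "tumor_category": adm.tumor_category() or "none",
    } for adm in cohort]
    return pd.DataFrame(rows, index=[adm.admission_id for adm in cohort])


def chi_square(table: np.ndarray | list, yates: bool = False) -> tuple[float, float]:
    """χ² test of independence on a contingency table; two-sided p."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=yates)
    return float(stat), float(p)


def univariate_screen(
    cohort: Cohort,
    ades: list[ADERecord],
    outcome: Literal["ADE", "SAE"] = "ADE",
    yates: bool = False,
) -> dict[str, tuple[float, float]]:
    """Two-group univariate tests per covariate.

    Continuous covariates: two-sample t-test (two-sided).  Categorical:
    χ² on the covariate × outcome contingency table (Yates optional).
    Degenerate variables (zero variance, empty margins) are skipped.
    """
    y = outcome_labels(cohort, ades, outcome)
    X = covariate_frame(cohort)
    results: dict[str, tuple[float, float]] = {}
    for var, kind in SCREEN_VARIABLES.items():
        col = X[var]
        if kind == "continuous":
            a = col[y == 1].astype(float)
            b = col[y == 0].astype(float)
            if len(a) < 2 or len(b) < 2 or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
                warnings.warn(f"skipping degenerate continuous variable {var!r}")
                continue
            stat, p = stats.ttest_ind(a, b)
            results[var] = (float(stat), float(p))
        else:
            table = pd.crosstab(col, y)
            if table.shape[0] < 2 or table.shape[1] < 2 or (table.values.sum(axis=1) == 0).any():
                warnings.warn(f"skipping degenerate categorical variable {var!r}")
                continue
            results[var] = chi_square(table.values, yates=yates)
    return results


def fit_logistic(X: pd.DataFrame, y: pd.Series | np.ndarray) -> dict:
    """Maximum-likelihood logistic fit; ORs with Wald 95% CIs.

    Returns ``terms`` (var -> (OR, ci_low, ci_high, p)), ``converged`` and
    ``separation_flags``.  Complete separation is flagged per variable
    rather than silently estimated.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        try:
            res = model.fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            return {"terms": {}, "converged": False,
                    "separation_flags": list(X.columns)}
    terms: dict[str, tuple[float, float, float, float]] = {}
    flags: list[str] = []
    ci = res.conf_int()
    for var in X.columns:
        coef = res.params[var]
        se = res.bse[var]
        if not np.isfinite(se) or se > 1e3 or abs(coef) > 20:
            flags.append(var)
            continue
        terms[var] = (float(np.exp(coef)), float(np.exp(ci.loc[var, 0])),
                      float(np.exp(ci.loc[var, 1])), float(res.pvalues[var]))
    return {"terms": terms, "converged": converged, "separation_flags": flags}


def fit_risk_model(
    cohort: Cohort,
    ades: list[ADERecord],
    outcome: Literal["ADE", "SAE"] = "ADE",
    variables: Optional[list[str]] = None,
    entry_p: float = 0.05,
) -> RiskFactorResult:
    """Univariate screen then multivariate logistic model.

    ``variables`` defaults to every screened covariate with univariate
    P < ``entry_p``.  Categorical covariates enter as indicator columns.
    """
    uni = univariate_screen(cohort, ades, outcome)
    if variables is None:
        variables = [v for v, (_, p) in uni.items() if p < entry_p]
    X = covariate_frame(cohort)
    cols = []
    for var in variables:
        if SCREEN_VARIABLES.get(var) == "categorical" and X[var].dtype == object:
            dummies = pd.get_dummies(X[var], prefix=var, drop_first=True)
            cols.append(dummies)
        else:
            cols.append(X[[var]])
    if not cols:
        return RiskFactorResult(outcome=outcome, converged=True, n=len(cohort),
                                univariate=uni, model_terms={})
    design = pd.concat(cols, axis=1)
    y = outcome_labels(cohort, ades, outcome)
    fit = fit_logistic(design, y)
    return RiskFactorResult(
        outcome=outcome, converged=fit["converged"], n=len(cohort),
        univariate=uni, model_terms=fit["terms"],
        separation_flags=fit["separation_flags"])
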