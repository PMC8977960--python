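"""Cohort-level statistics: group tests, correlations, standardized OLS.

Mirrors the analysis plan of the source study: Welch t tests (quantitative)
and chi-square tests (categorical) between non-obese and obese subjects,
Pearson correlations of MRI- and BIA-based muscle measures overall and by
obesity stratum, and linear regression of standardized outcomes on
standardized predictors adjusted for age and sex.  A standardized simple
regression slope equals the Pearson correlation, which is how the
"unadjusted estimate" columns of the association table arise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "GroupComparison",
    "standardize",
    "pearson_r",
    "standardized_ols",
    "compare_groups",
    "bonferroni",
    "run_full_analysis",
    "MRI_MEASURES",
    "BIA_ANTHRO_PREDICTORS",
]

MRI_MEASURES = ("ammi_total", "ammi_fatfree")
BIA_ANTHRO_PREDICTORS = (
    "lean_body_mass_index",
    "appendicular_muscle_mass_index",
    "smi_bia",
    "bmi",
    "hip",
    "waist",
)


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    adjusted_for: tuple = ()
    stratum: str = "all"

    def __post_init__(self):
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t" or "chi2"
    statistic: float
    p_value: float
    group_summary: dict = field(default_factory=dict)
    bonferroni_m: int | None = None
    p_adjusted: float | None = None


def standardize(x) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (denominator n - 1)."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("standardize needs at least two observations")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant (zero-variance) variable")
    return (arr - arr.mean()) / sd


def pearson_r(x, y):
    """Pearson correlation with its t-distribution p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson_r undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def standardized_ols(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple = ("age", "sex"),
    stratum: str = "all",
) -> AssociationResult:
    """OLS of standardized outcome on standardized predictor (+ covariates).

    Binary columns (e.g. sex) are coded 0/1 and then standardized like any
    other covariate.  Returns the predictor's slope with Wald 95 % CI using
    the t critical value at residual degrees of freedom.
    """
    cols = [outcome, predictor, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"missing required columns: {missing}")
    df = data[cols].copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "male").astype(float)
    df = df.astype(float).dropna()
    if len(df) < max(10, len(cols) + 2):
        raise ValueError(f"too few complete cases (n={len(df)}) for {cols}")
    try:
        z = {c: standardize(df[c].to_numpy()) for c in cols}
    except ValueError as exc:
        raise ValueError(f"degenerate column among {cols}: {exc}") from exc
    design = sm.add_constant(
        np.column_stack([z[predictor]] + [z[c] for c in covariates])
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"rank-deficient design for columns {cols}")
    fit = sm.OLS(z[outcome], design).fit()
    ci = fit.conf_int(alpha=0.05)
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        estimate=float(fit.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        n=len(df),
        adjusted_for=tuple(covariates),
        stratum=stratum,
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def compare_groups(
    data: pd.DataFrame,
    variable: str,
    group: str = "obese",
    kind: str | None = None,
    welch: bool = True,
    bonferroni_m: int | None = None,
) -> GroupComparison:
    """Two-group comparison between the non-obese and obese strata.

    Quantitative variables use the t test (Welch by default, Student when
    ``welch=False``); categorical/boolean variables a chi-square test on the
    2 x k contingency table without continuity correction.
    """
    if variable not in data.columns or group not in data.columns:
        raise KeyError(f"missing column {variable!r} or {group!r}")
    df = data[[variable, group]].dropna()
    groups = df[group].unique()
    if len(groups) != 2:
        raise ValueError(f"grouping column {group!r} must have exactly 2 levels")
    g0 = df.loc[~df[group].astype(bool), variable]
    g1 = df.loc[df[group].astype(bool), variable]
    if g0.empty or g1.empty:
        raise ValueError("both strata must be nonempty")
    if kind is None:
        kind = "t" if pd.api.types.is_float_dtype(df[variable]) else "chi2"
    if kind == "t":
        if len(g0) < 2 or len(g1) < 2:
            raise ValueError("t test needs n >= 2 per group")
        if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
            warnings.warn(
                f"degenerate t test for {variable!r}: zero variance in both groups",
                stacklevel=2,
            )
            same = g0.mean() == g1.mean()
            stat, p = (0.0, 1.0) if same else (np.inf, 0.0)
        else:
            stat, p = sps.ttest_ind(g0, g1, equal_var=not welch)
        summary = {
            "non_obese": (g0.mean(), g0.std(ddof=1), len(g0)),
            "obese": (g1.mean(), g1.std(ddof=1), len(g1)),
        }
    elif kind == "chi2":
        table = pd.crosstab(df[group], df[variable])
        if table.shape[1] < 2:
            warnings.warn(
                f"degenerate chi2 for {variable!r}: single observed category",
                stacklevel=2,
            )
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        summary = {str(k): tuple(v) for k, v in table.iterrows()}
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    p_adj = bonferroni(float(p), bonferroni_m) if bonferroni_m else None
    return GroupComparison(
        variable=variable,
        test=kind,
        statistic=float(stat),
        p_value=float(p),
        group_summary=summary,
        bonferroni_m=bonferroni_m,
        p_adjusted=p_adj,
    )


# -- full report ---------------------------------------------------------------

_REQUIRED_COHORT = {"subject_id", "age", "sex", "obese", "bmi", "waist", "hip",
                    "lean_body_mass_index", "appendicular_muscle_mass_index",
                    "smi_bia"}
_REQUIRED_MEASURES = {"subject_id", "ammi_total", "ammi_fatfree", "ratio",
                      "pdff_muscle"}


def _check_schema(df, required, label):
    missing = sorted(required - set(df.columns))
    if missing:
        raise KeyError(f"{label} table is missing columns: {missing}")


def _stratum_frames(df):
    yield "all", df
    yield "non_obese", df[~df["obese"].astype(bool)]
    yield "obese", df[df["obese"].astype(bool)]


def run_full_analysis(
    cohort: pd.DataFrame, measures: pd.DataFrame, bonferroni_m: int | None = None
) -> dict:
    """Produce the three report tables from a joined cohort/measures pair.

    Returns a dict of DataFrames:

    * ``descriptives`` -- stratified mean +- SD per body-composition variable
      with the non-obese vs obese test (optionally Bonferroni-adjusted);
    * ``correlations`` -- Pearson r of each MRI measure with each BIA /
      anthropometric predictor, overall and per obesity stratum;
    * ``associations`` -- unadjusted and age/sex-adjusted standardized
      regression estimates with 95 % CIs for the same pairs.
    """
    _check_schema(cohort, _REQUIRED_COHORT, "cohort")
    _check_schema(measures, _REQUIRED_MEASURES, "measures")
    df = cohort.merge(measures, on="subject_id", how="inner", validate="1:1")
    if df.empty:
        raise ValueError("cohort and measures share no subject_ids")

    desc_vars = [
        "height", "weight", "bmi", "waist", "hip",
        "total_body_fat_mass_index", "lean_body_mass_index",
        "appendicular_muscle_mass_index", "smi_bia",
        "csa_total", "ammi_total", "csa_fatfree", "ammi_fatfree",
        "ratio", "pdff_muscle", "vat", "sat",
    ]
    rows = []
    for var in desc_vars:
        if var not in df.columns:
            continue
        try:
            cmp_res = compare_groups(df, var, bonferroni_m=bonferroni_m)
        except ValueError as exc:
            warnings.warn(f"skipping test for {var!r}: {exc}", stacklevel=2)
            cmp_res = None
        sub = df[[var, "obese"]].dropna()
        g0 = sub.loc[~sub["obese"].astype(bool), var]
        g1 = sub.loc[sub["obese"].astype(bool), var]
        rows.append({
            "variable": var,
            "mean_all": sub[var].mean(), "sd_all": sub[var].std(ddof=1),
            "mean_non_obese": g0.mean(), "sd_non_obese": g0.std(ddof=1),
            "mean_obese": g1.mean(), "sd_obese": g1.std(ddof=1),
            "p_value": cmp_res.p_value if cmp_res else np.nan,
            "p_adjusted": (cmp_res.p_adjusted if cmp_res and cmp_res.p_adjusted
                           is not None else np.nan),
        })
    descriptives = pd.DataFrame(rows)

    corr_rows = []
    for outcome in MRI_MEASURES:
        for predictor in BIA_ANTHRO_PREDICTORS:
            for label, frame in _stratum_frames(df):
                sub = frame[[outcome, predictor]].dropna()
                try:
                    r, p = pearson_r(sub[outcome], sub[predictor])
                except ValueError as exc:
                    warnings.warn(
                        f"degenerate correlation {outcome}~{predictor} "
                        f"({label}): {exc}", stacklevel=2,
                    )
                    r, p = np.nan, np.nan
                corr_rows.append({
                    "outcome": outcome, "predictor": predictor,
                    "stratum": label, "r": r, "p_value": p, "n": len(sub),
                })
    correlations = pd.DataFrame(corr_rows)

    assoc_rows = []
    for outcome in MRI_MEASURES:
        for predictor in BIA_ANTHRO_PREDICTORS:
            for label, frame in _stratum_frames(df):
                try:
                    unadj = standardized_ols(frame, outcome, predictor,
                                             covariates=(), stratum=label)
                    adj = standardized_ols(frame, outcome, predictor,
                                           covariates=("age", "sex"),
                                           stratum=label)
                except ValueError as exc:
                    warnings.warn(
                        f"degenerate association {outcome}~{predictor} "
                        f"({label}): {exc}", stacklevel=2,
                    )
                    continue
                assoc_rows.append({
                    "outcome": outcome, "predictor": predictor, "stratum": label,
                    "estimate_unadjusted": unadj.estimate,
                    "ci_low_unadjusted": unadj.ci_low,
                    "ci_high_unadjusted": unadj.ci_high,
                    "p_unadjusted": unadj.p_value,
                    "estimate_adjusted": adj.estimate,
                    "ci_low_adjusted": adj.ci_low,
                    "ci_high_adjusted": adj.ci_high,
                    "p_adjusted": adj.p_value,
                    "n": adj.n,
                })
    associations = pd.DataFrame(assoc_rows)

    return {
        "descriptives": descriptives,
        "correlations": correlations,
        "associations": associations,
    }
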