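"""Statistical machinery against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from musclemap import (
    bonferroni,
    compare_groups,
    pearson_r,
    run_full_analysis,
    standardize,
    standardized_ols,
)


def ols_normal_equations(y, X):
    """Independent oracle: slope vector via (X'X)^{-1} X'y with intercept."""
    X1 = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(X1.T @ X1, X1.T @ y)


def test_standardize_basic():
    out = standardize([1.0, 2.0, 3.0])
    assert np.allclose(out, [-1.0, 0.0, 1.0])
    assert standardize(out) == pytest.approx(out)  # idempotent
    with pytest.raises(ValueError, match="constant"):
        standardize([4.0, 4.0, 4.0])
    with pytest.raises(ValueError):
        standardize([1.0])


def test_pearson_perfect_and_null(rng):
    x = rng.normal(size=50)
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    x = rng.normal(size=10_000)
    y = rng.normal(size=10_000)
    r, _ = pearson_r(x, y)
    assert abs(r) < 0.03
    with pytest.raises(ValueError):
        pearson_r(x, np.zeros_like(x))


def test_pearson_matches_covariance_definition(rng):
    x, y = rng.normal(size=200), rng.normal(size=200)
    r, _ = pearson_r(x, y)
    manual = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
    assert r == pytest.approx(manual, abs=1e-12)


def test_ols_unadjusted_equals_pearson(rng):
    df = pd.DataFrame({
        "y": rng.normal(size=80), "x": rng.normal(size=80),
    })
    res = standardized_ols(df, "y", "x", covariates=())
    r, p = pearson_r(df["x"], df["y"])
    assert res.estimate == pytest.approx(r, abs=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-9)


def test_ols_matches_normal_equations(rng):
    n = 150
    df = pd.DataFrame({
        "age": rng.normal(55, 9, n),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "x": rng.normal(size=n),
    })
    df["y"] = 0.5 * df["x"] + 0.02 * df["age"] + rng.normal(size=n)
    res = standardized_ols(df, "y", "x", covariates=("age", "sex"))
    z = {c: standardize(df[c] if c != "sex" else (df["sex"] == "male").astype(float))
         for c in ["y", "x", "age", "sex"]}
    beta = ols_normal_equations(z["y"], np.column_stack([z["x"], z["age"], z["sex"]]))
    assert res.estimate == pytest.approx(beta[1], abs=1e-9)
    assert res.ci_low <= res.estimate <= res.ci_high
    assert res.n == n and res.adjusted_for == ("age", "sex")


def test_ols_null_behaviour(rng):
    n = 1000
    df = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)})
    res = standardized_ols(df, "y", "x", covariates=())
    assert abs(res.estimate) < 0.1


def test_ols_rank_deficiency(rng):
    n = 60
    x = rng.normal(size=n)
    df = pd.DataFrame({"y": rng.normal(size=n), "x": x, "x2": 2 * x,
                       "sex": ["male"] * 30 + ["female"] * 30,
                       "age": rng.normal(50, 5, n)})
    with pytest.raises(ValueError, match="rank-deficient"):
        standardized_ols(df, "y", "x", covariates=("x2",))


def test_compare_groups_t_and_chi2(rng):
    n = 400
    df = pd.DataFrame({
        "obese": np.repeat([False, True], n // 2),
        "v": rng.normal(size=n),
        "flag": rng.random(n) < 0.4,
    })
    res = compare_groups(df, "v")
    assert res.test == "t" and 0 <= res.p_value <= 1
    res2 = compare_groups(df, "flag")
    assert res2.test == "chi2"
    # identical groups -> statistic 0, p in the 1 region
    df2 = pd.DataFrame({"obese": [False] * 4 + [True] * 4,
                        "v": [1.0, 2.0, 3.0, 4.0] * 2})
    res3 = compare_groups(df2, "v")
    assert res3.statistic == pytest.approx(0.0)
    assert res3.p_value == pytest.approx(1.0)


def test_bonferroni_rule():
    assert bonferroni(0.02, 3) == pytest.approx(0.06)
    assert bonferroni(0.5, 3) == 1.0
    with pytest.raises(ValueError):
        bonferroni(0.02, 0)


def test_t_test_power_against_closed_form(rng):
    """Mean gap 0.5 SD at n = 200/200: closed-form power ~ 0.999."""
    reps, n = 1000, 200
    a = rng.normal(0.0, 1.0, (reps, n))
    b = rng.normal(0.5, 1.0, (reps, n))
    rejections = 0
    from scipy import stats as sps

    _, pvals = sps.ttest_ind(a, b, axis=1, equal_var=False)
    rejections = (pvals < 0.05).sum()
    assert rejections / reps > 0.99


def test_welch_vs_student_switch(rng):
    df = pd.DataFrame({
        "obese": np.repeat([False, True], [150, 50]),
        "v": np.concatenate([rng.normal(0, 1, 150), rng.normal(0, 4, 50)]),
    })
    welch = compare_groups(df, "v", welch=True)
    student = compare_groups(df, "v", welch=False)
    assert welch.p_value != student.p_value


def test_run_full_analysis_outputs(cohort_model, default_config):
    from musclemap.phantom import simulate_images
    from musclemap.quant import quantify_subject
    from musclemap.io import measures_to_row

    cohort = cohort_model.sample(120, seed=13)
    rows = [
        measures_to_row(row["subject_id"], quantify_subject(pm, ms, row["height"]))
        for row, pm, ms, _ in simulate_images(cohort, default_config, seed=13)
    ]
    measures = pd.DataFrame(rows)
    tables = run_full_analysis(cohort, measures, bonferroni_m=3)
    assert set(tables) == {"descriptives", "correlations", "associations"}
    corr = tables["correlations"]
    # stratification consistency: stratum ns sum to the pooled n
    for (outcome, predictor), grp in corr.groupby(["outcome", "predictor"]):
        g = grp.set_index("stratum")["n"]
        assert g["non_obese"] + g["obese"] == g["all"]
    assoc = tables["associations"]
    # unadjusted standardized estimate equals the Pearson r for each pair
    merged = assoc.merge(corr, on=["outcome", "predictor", "stratum"])
    assert np.allclose(merged["estimate_unadjusted"], merged["r"], atol=1e-9)
    assert (tables["descriptives"]["p_adjusted"].dropna()
            >= tables["descriptives"]["p_value"].dropna()).all()


def test_run_full_analysis_schema_error(cohort_model):
    cohort = cohort_model.sample(30, seed=2).drop(columns=["sex"])
    measures = pd.DataFrame({
        "subject_id": cohort["subject_id"], "ammi_total": 1.0,
        "ammi_fatfree": 1.0, "ratio": 50.0, "pdff_muscle": 10.0,
    })
    with pytest.raises(KeyError, match="sex"):
        run_full_analysis(cohort, measures)


def test_degenerate_cohort_warns_but_runs(default_config):
    # two identical subjects per stratum: tests degrade gracefully
    base = {
        "age": 50.0, "height": 1.7, "bmi": 25.0, "waist": 90.0, "hip": 100.0,
        "lean_body_mass_index": 18.0, "appendicular_muscle_mass_index": 7.5,
        "smi_bia": 9.0,
    }
    rows = []
    for i in range(4):
        r = dict(base)
        r["subject_id"] = f"D{i}"
        r["sex"] = "male"
        r["obese"] = i >= 2
        if r["obese"]:
            r["bmi"] = 32.0
        rows.append(r)
    cohort = pd.DataFrame(rows)
    measures = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "ammi_total": 3000.0, "ammi_fatfree": 1700.0,
        "ratio": 56.7, "pdff_muscle": 11.0,
        "csa_total": 8700.0, "csa_fatfree": 4900.0,
    })
    with pytest.warns(UserWarning):
        tables = run_full_analysis(cohort, measures)
    assert not tables["descriptives"].empty
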