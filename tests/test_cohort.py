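"""Synthetic cohort generator: determinism, internal consistency, calibration."""

import numpy as np
import pandas as pd
import pytest

from musclemap import CohortModel, ConfigError, GeneratorConfig, generate_cohort
from musclemap import janssen_smm, smi_bia
from musclemap.calibration import (
    match_truncnorm,
    nearest_correlation,
    solve_within_correlation,
)


def test_same_seed_bitwise_identical(cohort_model):
    a = cohort_model.sample(100, seed=5)
    b = cohort_model.sample(100, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = cohort_model.sample(100, seed=6)
    assert not a["bmi"].equals(c["bmi"])


def test_record_invariants(small_cohort):
    c = small_cohort
    assert len(c) == 60
    assert np.allclose(c["bmi"], c["weight"] / c["height"] ** 2)
    assert ((c["bmi"] >= 30) == c["obese"]).all()
    assert c["target_ratio"].between(0, 1, inclusive="neither").all()
    assert c["target_pdff_muscle"].between(0, 100).all()
    assert (c["target_csa_total"] > 0).all()
    assert (c["resistance"] > 0).all()
    assert c["sex"].isin(["male", "female"]).all()


def test_bia_roundtrip_consistency(small_cohort):
    c = small_cohort
    smi = smi_bia(
        janssen_smm(c["resistance"], c["height"] * 100, c["sex"].to_numpy(),
                    c["age"]),
        c["height"],
    )
    assert np.max(np.abs(smi - c["smi_bia"]) / c["smi_bia"]) < 1e-9


def test_obese_count_expectation(cohort_model):
    """With the study's stratum weights the expected obese count is 95/335."""
    counts = [cohort_model.sample(335, seed=s)["obese"].sum() for s in range(10)]
    assert abs(np.mean(counts) - 95) < 10  # SE of the mean ~ 2.6


def test_independence_case():
    """All-zero correlation targets give uncorrelated variables."""
    cfg = GeneratorConfig(correlation_targets=[])
    c = CohortModel(cfg).sample(25_000, seed=3)
    # stratify to remove mixture-induced correlation
    sub = c[(~c["obese"]) & (c["sex"] == "male")]
    for a, b in [("age", "bmi"), ("height", "smi_bia"),
                 ("target_ammi_total", "lean_body_mass_index")]:
        r = np.corrcoef(sub[a], sub[b])[0, 1]
        assert abs(r) < 0.03


def test_marginal_calibration(cohort_model):
    """Pooled means/SDs track the printed cohort table at n = 10 000."""
    c = cohort_model.sample(10_000, seed=17)
    targets = {  # pooled mean, sd from the stratum-weighted printed values
        "smi_bia": (9.212, 1.6),
        "bmi": (27.825, 4.7),
        "target_ammi_total": (2954.6, 585.4),
        "target_ammi_fatfree": (1709.5, 492.5),
    }
    for var, (mean, sd) in targets.items():
        assert c[var].mean() == pytest.approx(mean, rel=0.01), var
        assert c[var].std() == pytest.approx(sd, rel=0.03), var


def test_correlation_calibration(cohort_model):
    """Targeted pooled correlations are reproduced within +-0.03 at n = 10 000."""
    c = cohort_model.sample(10_000, seed=29)
    pairs = {
        ("target_ammi_total", "smi_bia"): 0.67,
        ("target_ammi_fatfree", "smi_bia"): 0.58,
        ("target_ammi_fatfree", "lean_body_mass_index"): 0.48,
        ("target_ammi_total", "waist"): 0.53,
    }
    for (a, b), target in pairs.items():
        r = np.corrcoef(c[a], c[b])[0, 1]
        assert r == pytest.approx(target, abs=0.03), (a, b)


def test_stratified_correlation_regimes(cohort_model):
    """MRI-BIA concordance is stronger in non-obese than obese subjects."""
    c = cohort_model.sample(10_000, seed=31)
    no, ob = c[~c["obese"]], c[c["obese"]]
    r_no = np.corrcoef(no["target_ammi_total"], no["lean_body_mass_index"])[0, 1]
    r_ob = np.corrcoef(ob["target_ammi_total"], ob["lean_body_mass_index"])[0, 1]
    assert r_no == pytest.approx(0.74, abs=0.03)
    assert r_ob == pytest.approx(0.56, abs=0.04)
    assert r_no > r_ob


def test_config_validation():
    with pytest.raises(ConfigError):
        GeneratorConfig(n_subjects=1)
    with pytest.raises(ConfigError):
        GeneratorConfig(obese_fraction=0.0)
    with pytest.raises(ConfigError):
        GeneratorConfig(septum_fat_fraction_range=(15.0, 30.0))
    marg = GeneratorConfig().stratum_marginals.copy()
    marg.loc[marg["variable"] == "age", "sd"] = -1.0
    with pytest.raises(ConfigError, match="sd"):
        GeneratorConfig(stratum_marginals=marg)


def test_generate_cohort_wrapper(default_config):
    c = generate_cohort(default_config, seed=8)
    assert len(c) == default_config.n_subjects


def test_match_truncnorm_recovers_moments():
    from scipy import stats

    for mean, sd, lo, hi in [(122.6, 76.4, 5.0, np.inf),
                             (25.5, 2.7, 14.0, 30.0),
                             (33.7, 3.3, 30.0, 65.0)]:
        mu, sigma, a, b = match_truncnorm(mean, sd, lo, hi)
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert m == pytest.approx(mean, abs=1e-6)
        assert np.sqrt(v) == pytest.approx(sd, abs=1e-6)


def test_solve_within_correlation_identity_when_homogeneous():
    # equal stratum means reduce the pooled solve to the within value
    rho = solve_within_correlation(0.5, [0.5, 0.5], [1, 1], [2, 2], [3, 3], [4, 4])
    assert rho == pytest.approx(0.5)


def test_nearest_correlation_projects_to_psd():
    m = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
    proj, change = nearest_correlation(m)
    assert np.linalg.eigvalsh(proj).min() >= 0
    assert np.allclose(np.diag(proj), 1.0)
    assert change > 0.1  # that matrix is badly indefinite
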