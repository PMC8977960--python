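"""Seeded synthetic cohort generation via a stratified Gaussian copula.

Subjects are drawn in two stages: first the stratum (obese with the
configured probability, then sex with the stratum's male fraction), then the
continuous covariate vector from a Gaussian copula whose marginals are
moment-matched truncated normals per (obesity x sex) stratum and whose
latent correlation matrix is calibrated so the printed pooled correlations
between the MRI muscle indices and the BIA indices are reproduced.

Derived fields are made mutually consistent afterwards: weight follows from
BMI and height, the obesity flag from the BMI truncation boundary, and BIA
resistance is obtained by algebraically inverting the Janssen equation from
the sampled SMI, so recomputing SMI from (resistance, height, sex, age)
round-trips exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from . import calibration
from .bia import invert_janssen, janssen_smm, smi_bia
from .config import ConfigError, GeneratorConfig

__all__ = ["CohortModel", "generate_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "subject_id", "age", "sex", "height", "weight", "bmi", "waist", "hip",
    "obese", "resistance", "lean_body_mass_index",
    "appendicular_muscle_mass_index", "total_body_fat_mass_index",
    "smm_bia", "smi_bia", "vat", "sat", "glucose_status", "hypertension",
    "target_ammi_total", "target_ammi_fatfree", "target_csa_total",
    "target_ratio", "target_pdff_muscle",
]


class CohortModel:
    """Resolved sampling model: matched marginals + latent correlations.

    Construction performs all deterministic calibration work (truncated
    normal moment matching, pooled-to-within correlation solves, PSD
    projection) once; :meth:`sample` can then be called repeatedly.
    """

    def __init__(self, config: GeneratorConfig):
        self.config = config
        self.variables = list(calibration.VARIABLES)
        self._index = {v: i for i, v in enumerate(self.variables)}
        self.strata = [
            (ob, sex)
            for ob in calibration.OBESITY_STRATA
            for sex in calibration.SEXES
        ]
        self.weights = calibration.stratum_weights(
            config.obese_fraction, config.male_fraction
        )
        # marginal parameters per stratum: arrays of (mu, sigma, a, b)
        self.marginal_params = {}
        for stratum in self.strata:
            params = []
            for var in self.variables:
                mean, sd, lo, hi = config.marginal(var, *stratum)
                params.append(calibration.match_truncnorm(mean, sd, lo, hi))
            self.marginal_params[stratum] = np.array(params)  # (n_var, 4)
        self.latent_corr, self.projection_change = self._build_latent_corr()
        self._chol = {
            ob: np.linalg.cholesky(self.latent_corr[ob])
            for ob in calibration.OBESITY_STRATA
        }

    # -- correlation assembly -------------------------------------------------

    def _pair_stats(self, var, strata):
        cfg = self.config
        means, sds = [], []
        for st in strata:
            m, s, _, _ = cfg.marginal(var, *st)
            means.append(m)
            sds.append(s)
        return np.array(means), np.array(sds)

    def _build_latent_corr(self):
        n = len(self.variables)
        mats = {ob: np.eye(n) for ob in calibration.OBESITY_STRATA}
        set_mask = {ob: np.eye(n, dtype=bool) for ob in calibration.OBESITY_STRATA}
        # entries pinned during the PSD solve: calibrated / chosen, not defaults
        fixed_mask = {ob: np.zeros((n, n), dtype=bool)
                      for ob in calibration.OBESITY_STRATA}

        def put(ob, a, b, rho, is_default):
            i, j = self._index[a], self._index[b]
            if is_default and set_mask[ob][i, j]:
                return
            mats[ob][i, j] = mats[ob][j, i] = rho
            set_mask[ob][i, j] = set_mask[ob][j, i] = True
            if not is_default:
                fixed_mask[ob][i, j] = fixed_mask[ob][j, i] = True

        for tgt in self.config.correlation_targets:
            a, b = tgt["a"], tgt["b"]
            if a not in self._index or b not in self._index:
                raise ConfigError(f"unknown variable in correlation target: {a}, {b}")
            default = bool(tgt.get("default", False))
            if "within" in tgt:
                for ob in calibration.OBESITY_STRATA:
                    put(ob, a, b, float(tgt["within"]), default)
            elif "pooled" in tgt:
                w = [self.weights[s] for s in self.strata]
                ma, sa = self._pair_stats(a, self.strata)
                mb, sb = self._pair_stats(b, self.strata)
                rho = calibration.solve_within_correlation(
                    float(tgt["pooled"]), w, ma, sa, mb, sb
                )
                for ob in calibration.OBESITY_STRATA:
                    put(ob, a, b, rho, default)
            elif "by_obesity" in tgt:
                for ob, target in tgt["by_obesity"].items():
                    strata = [(ob, sex) for sex in calibration.SEXES]
                    w = [self.weights[s] for s in strata]
                    ma, sa = self._pair_stats(a, strata)
                    mb, sb = self._pair_stats(b, strata)
                    rho = calibration.solve_within_correlation(
                        float(target), w, ma, sa, mb, sb
                    )
                    put(ob, a, b, rho, default)
            else:
                raise ConfigError(
                    f"correlation target for ({a}, {b}) needs one of "
                    "'pooled', 'by_obesity', 'within'"
                )
        out, changes = {}, {}
        for ob, mat in mats.items():
            proj, change = calibration.constrained_nearest_correlation(
                mat, fixed_mask[ob]
            )
            if change > 0.02:
                warnings.warn(
                    f"PSD projection moved {ob} correlations by up to "
                    f"{change:.3f}; calibration targets may be distorted",
                    stacklevel=2,
                )
            try:
                np.linalg.cholesky(proj)
            except np.linalg.LinAlgError as exc:
                raise ConfigError(
                    f"correlation matrix for {ob} stratum singular after "
                    "projection"
                ) from exc
            out[ob] = proj
            changes[ob] = change
        return out, changes

    # -- sampling -------------------------------------------------------------

    def sample(self, n_subjects: int | None = None, seed: int | None = None):
        """Draw a cohort table; identical (config, seed) gives identical output."""
        cfg = self.config
        n = cfg.n_subjects if n_subjects is None else int(n_subjects)
        if n < 2:
            raise ConfigError("n_subjects must be >= 2")
        rng = np.random.default_rng(cfg.seed if seed is None else seed)

        obese = rng.random(n) < cfg.obese_fraction
        p_male = np.where(
            obese, cfg.male_fraction["obese"], cfg.male_fraction["non_obese"]
        )
        male = rng.random(n) < p_male

        n_var = len(self.variables)
        x = np.empty((n, n_var))
        for ob_label, ob_flag in (("non_obese", False), ("obese", True)):
            chol = self._chol[ob_label]
            for sex_label, sex_flag in (("male", True), ("female", False)):
                idx = np.flatnonzero((obese == ob_flag) & (male == sex_flag))
                if idx.size == 0:
                    continue
                z = rng.standard_normal((idx.size, n_var)) @ chol.T
                u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
                params = self.marginal_params[(ob_label, sex_label)]
                for j in range(n_var):
                    mu, sigma, a, b = params[j]
                    x[idx, j] = stats.truncnorm.ppf(
                        u[:, j], a, b, loc=mu, scale=sigma
                    )

        df = pd.DataFrame(x, columns=self.variables)
        df.insert(0, "subject_id", [f"S{i + 1:05d}" for i in range(n)])
        df["sex"] = np.where(male, "male", "female")
        df["obese"] = df["bmi"] >= 30.0  # equals the stratum flag by truncation
        assert (df["obese"].to_numpy() == obese).all()
        df["weight"] = df["bmi"] * df["height"] ** 2
        df["resistance"] = invert_janssen(
            df["smi_bia"].to_numpy(), df["height"].to_numpy() * 100.0,
            df["sex"].to_numpy(), df["age"].to_numpy(),
        )
        df["smm_bia"] = janssen_smm(
            df["resistance"].to_numpy(), df["height"].to_numpy() * 100.0,
            df["sex"].to_numpy(), df["age"].to_numpy(),
        )
        # categorical risk factors at the printed stratum prevalences
        rates = cfg.risk_factor_rates
        p_glu = np.where(obese, rates["impaired_glucose"]["obese"],
                         rates["impaired_glucose"]["non_obese"])
        p_hyp = np.where(obese, rates["hypertension"]["obese"],
                         rates["hypertension"]["non_obese"])
        df["glucose_status"] = np.where(
            rng.random(n) < p_glu, "impaired", "normal"
        )
        df["hypertension"] = rng.random(n) < p_hyp

        # MRI targets: AMMI values were sampled jointly in the copula; the
        # per-subject CSA and ratio follow from height.
        df = df.rename(
            columns={"ammi_total": "target_ammi_total",
                     "ammi_fatfree": "target_ammi_fatfree",
                     "pdff_muscle": "target_pdff_muscle"}
        )
        df["target_ratio"] = np.clip(
            df["target_ammi_fatfree"] / df["target_ammi_total"], 0.05, 0.98
        )
        df["target_ammi_fatfree"] = df["target_ratio"] * df["target_ammi_total"]
        df["target_csa_total"] = df["target_ammi_total"] * df["height"] ** 2
        return df[COHORT_COLUMNS]


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Convenience wrapper: resolve the model and draw one cohort."""
    return CohortModel(config).sample(config.n_subjects, seed)
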