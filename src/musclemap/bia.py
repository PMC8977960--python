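"""Bioelectrical-impedance (BIA) skeletal muscle mass.

Implements the Janssen regression equation that converts whole-body ohmic
resistance (50 kHz) into skeletal muscle mass (SMM, kg),

    SMM = height_cm**2 / resistance * 0.401 + sex * 3.825 - 0.071 * age + 5.102

with height in centimetres, resistance in ohms, sex coded male = 1 /
female = 0 and age in years, plus the height-squared normalisation that
yields the skeletal muscle index SMI_BIA (kg/m**2).

Only the printed SMM equation is modelled here.  The other BIA indices that
appear in the cohort table (total body fat mass index, lean body mass index,
appendicular muscle mass index) have no closed-form device equation and are
treated as generated covariates elsewhere; this module must not be mistaken
for a full BIA device model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SMM_RESISTANCE_COEF",
    "SMM_SEX_COEF",
    "SMM_AGE_COEF",
    "SMM_INTERCEPT",
    "janssen_smm",
    "smi_bia",
    "invert_janssen",
]

SMM_RESISTANCE_COEF = 0.401
SMM_SEX_COEF = 3.825
SMM_AGE_COEF = -0.071
SMM_INTERCEPT = 5.102


def _sex_code(sex):
    """Map 'male'/'female' (or 1/0) to the equation's 1/0 coding."""
    if isinstance(sex, str):
        try:
            return {"male": 1.0, "female": 0.0}[sex]
        except KeyError:
            raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    arr = np.asarray(sex)
    if arr.dtype.kind in "USO":
        mapped = np.where(arr == "male", 1.0, np.where(arr == "female", 0.0, np.nan))
        if np.isnan(mapped).any():
            raise ValueError("sex array contains values other than 'male'/'female'")
        return mapped
    return arr.astype(float)


def janssen_smm(resistance, height_cm, sex, age):
    """Skeletal muscle mass (kg) from the Janssen BIA equation.

    Parameters
    ----------
    resistance : float or array
        Ohmic resistance in ohms; must be > 0.
    height_cm : float or array
        Body height in centimetres; must be > 0.
    sex : {'male', 'female'} or {1, 0} (scalar or array)
    age : float or array
        Age in years; must be >= 0.
    """
    resistance = np.asarray(resistance, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(resistance <= 0):
        raise ValueError("resistance must be positive (ohms)")
    if np.any(height_cm <= 0):
        raise ValueError("height_cm must be positive")
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    g = _sex_code(sex)
    smm = (
        height_cm**2 / resistance * SMM_RESISTANCE_COEF
        + g * SMM_SEX_COEF
        + age * SMM_AGE_COEF
        + SMM_INTERCEPT
    )
    return smm if smm.ndim else float(smm)


def smi_bia(smm_kg, height_m):
    """Skeletal muscle index (kg/m**2): SMM normalised to height squared."""
    height_m = np.asarray(height_m, dtype=float)
    if np.any(height_m <= 0):
        raise ValueError("height_m must be positive")
    out = np.asarray(smm_kg, dtype=float) / height_m**2
    return out if out.ndim else float(out)


def invert_janssen(smi_target, height_cm, sex, age):
    """Resistance (ohms) that reproduces a target SMI under the Janssen equation.

    Solves smi_target = janssen_smm(R, ...) / height_m**2 for R.  Used by the
    synthetic-cohort generator to make resistance consistent with a sampled
    SMI_BIA.  Raises if the implied resistance is non-positive, i.e. the
    target muscle mass does not exceed the sex/age intercept terms.
    """
    smi_target = np.asarray(smi_target, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(height_cm <= 0):
        raise ValueError("height_cm must be positive")
    g = _sex_code(sex)
    height_m = height_cm / 100.0
    smm = smi_target * height_m**2
    denom = smm - g * SMM_SEX_COEF - age * SMM_AGE_COEF - SMM_INTERCEPT
    bad = denom <= 0
    if np.any(bad):
        idx = np.atleast_1d(bad).nonzero()[0]
        raise ValueError(
            "target SMI implies non-positive resistance (muscle mass below the "
            f"sex/age intercept) for record index/indices {idx.tolist()}"
        )
    resistance = height_cm**2 * SMM_RESISTANCE_COEF / denom
    return resistance if resistance.ndim else float(resistance)
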