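"""Clinical covariate formulas: DuBois body surface area and CKD-EPI eGFR.

These are the two derived covariates of the cefazolin covariate model:
BSA scales the central volume of distribution and eGFR scales clearance.
"""

from __future__ import annotations

import numpy as np

#: µmol/L per mg/dL for serum creatinine.
CREATININE_UMOL_PER_MGDL = 88.4

# CKD-EPI 2009 creatinine equation, without the race term (the cohort this
# package emulates is central-European; the coefficient table is exposed so
# a different refit can be swapped in).
CKD_EPI_2009 = {
    "F": {"kappa": 0.7, "alpha": -0.329, "sex_factor": 1.018},
    "M": {"kappa": 0.9, "alpha": -0.411, "sex_factor": 1.0},
    "exponent": -1.209,
    "age_base": 0.993,
    "scale": 141.0,
}


def bsa_dubois(weight_kg, height_cm):
    """Body surface area (m²) by the DuBois & DuBois power law.

    BSA = 0.007184 · weight^0.425 · height^0.725
    """
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = 0.007184 * weight_kg**0.425 * height_cm**0.725
    return float(out) if out.ndim == 0 else out


def egfr_ckd_epi(scr_umol_l, age_years, sex, *, coefficients=CKD_EPI_2009):
    """Estimated glomerular filtration rate, mL/s per 1.73 m².

    CKD-EPI creatinine equation evaluated from serum creatinine in µmol/L
    (converted internally to mg/dL) and returned on the SI mL/s scale used
    throughout this package (divide mL/min/1.73 m² by 60).

    Parameters
    ----------
    scr_umol_l : float or array
        Serum creatinine, µmol/L.
    age_years : float or array
        Age in years.
    sex : str or array of str
        "M" or "F".
    """
    scr = np.asarray(scr_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("creatinine and age must be strictly positive")
    sex_arr = np.asarray(sex)
    female = sex_arr == "F"
    if not np.all(female | (sex_arr == "M")):
        raise ValueError("sex must be 'M' or 'F'")

    kappa = np.where(female, coefficients["F"]["kappa"], coefficients["M"]["kappa"])
    alpha = np.where(female, coefficients["F"]["alpha"], coefficients["M"]["alpha"])
    sex_factor = np.where(
        female, coefficients["F"]["sex_factor"], coefficients["M"]["sex_factor"]
    )
    scr_mgdl = scr / CREATININE_UMOL_PER_MGDL
    ratio = scr_mgdl / kappa
    egfr_ml_min = (
        coefficients["scale"]
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** coefficients["exponent"]
        * coefficients["age_base"] ** age
        * sex_factor
    )
    out = egfr_ml_min / 60.0
    return float(out) if out.ndim == 0 else out
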