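"""Seeded virtual cohorts emulating the cardiac-surgery cefazolin study.

The study design this module reproduces: 65 adults in three arms —
25 on minimally invasive extracorporeal circulation (MiECC), 20 on
standard extracorporeal circulation (ECC) and 20 without bypass — each
given a 2 g IV cefazolin bolus 30–60 min before incision, with blood
samples at 15/30/45/60/120/180 min after the dose plus one at the end of
surgery.  Covariates are drawn per arm from truncated log-normal
distributions anchored to the published median and observed range;
weight and height are sampled jointly (rank correlation 0.5) and eGFR is
always derived from sampled creatinine/age/sex through CKD-EPI, never
sampled directly.  Eligibility constraints (BMI 17–35 kg/m², creatinine
< 200 µmol/L) are enforced by rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import bsa_dubois, egfr_ckd_epi
from .dataset import ALL_COLUMNS, PKDataset
from .model import CovariateVector, PopulationModel, sample_individual, concentration

__all__ = ["CohortSpec", "generate_covariates", "generate_design",
           "simulate_observations", "simulate_cohort"]

#: z-score of the 99.5th normal percentile: the published range is treated
#: as the (0.5, 99.5) percentile band of the sampling distribution.
_Z_RANGE = 2.5758293035489004

#: Pearson correlation of the Gaussian copula giving Spearman rank
#: correlation 0.5 between weight and height.
_WT_HT_COPULA_R = 2.0 * np.sin(np.pi * 0.5 / 6.0)

# per-arm covariate table: median and observed (min, max)
_COVARIATE_TABLE = {
    "NONE": {
        "AGE": (72.0, 53.0, 86.0), "WT": (86.0, 51.0, 117.0),
        "HT": (171.0, 158.0, 194.0), "SCR": (84.0, 50.0, 188.0),
        "UREA": (4.9, 1.5, 12.2), "TPROT": (70.6, 60.3, 81.0),
        "ALB": (45.3, 35.2, 50.7), "BILI": (12.5, 5.0, 50.0),
    },
    "ECC": {
        "AGE": (68.0, 44.0, 82.0), "WT": (85.0, 71.0, 107.0),
        "HT": (176.0, 168.0, 185.0), "SCR": (90.0, 64.0, 145.0),
        "UREA": (5.3, 4.1, 9.4), "TPROT": (70.2, 60.7, 80.1),
        "ALB": (44.0, 35.1, 50.8), "BILI": (12.0, 4.0, 43.0),
    },
    "MIECC": {
        "AGE": (73.0, 53.0, 85.0), "WT": (89.0, 56.0, 117.0),
        "HT": (172.0, 156.0, 196.0), "SCR": (83.0, 57.0, 130.0),
        "UREA": (4.8, 3.0, 8.9), "TPROT": (73.5, 59.4, 84.3),
        "ALB": (45.0, 39.2, 51.0), "BILI": (11.0, 6.0, 51.0),
    },
}

_SURGERY_TABLE = {
    "NONE": (135.0, 81.0, 240.0),
    "ECC": (198.0, 155.0, 259.0),
    "MIECC": (191.0, 129.0, 384.0),
}

_SEX_COUNTS = {"NONE": (17, 3), "ECC": (19, 1), "MIECC": (19, 6)}  # (M, F)


@dataclass
class CohortSpec:
    """Design of a virtual cohort; defaults reproduce the 65-patient study."""

    n_per_arm: Dict[str, int] = field(
        default_factory=lambda: {"NONE": 20, "ECC": 20, "MIECC": 25}
    )
    sex_counts: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(_SEX_COUNTS)
    )
    covariate_table: Dict[str, Dict[str, Tuple[float, float, float]]] = field(
        default_factory=lambda: {a: dict(t) for a, t in _COVARIATE_TABLE.items()}
    )
    surgery_duration: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(_SURGERY_TABLE)
    )
    dose_mg: float = 2000.0
    incision_delay_min: Tuple[float, float] = (30.0, 60.0)
    nominal_times_min: Tuple[float, ...] = (15.0, 30.0, 45.0, 60.0, 120.0, 180.0)
    bmi_bounds: Tuple[float, float] = (17.0, 35.0)
    creatinine_max: float = 200.0

    def __post_init__(self):
        for arm, n in self.n_per_arm.items():
            if n < 1:
                raise ValueError(f"arm {arm} must have at least one subject")
        for arm, table in self.covariate_table.items():
            for name, (med, lo, hi) in table.items():
                if not (lo < hi):
                    raise ValueError(f"{arm}/{name}: range min must be below max")
                if not (lo <= med <= hi):
                    raise ValueError(f"{arm}/{name}: median outside its range")
        if np.any(np.diff(self.nominal_times_min) <= 0):
            raise ValueError("nominal sample times must be strictly increasing")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_arm.values())


def _lognormal_params(median: float, lo: float, hi: float) -> Tuple[float, float]:
    """Log-scale location/SD of the truncated sampling distribution.

    The SD is set so the untruncated (0.5, 99.5) percentiles bracket
    (lo, hi); the location is then corrected by a short fixed-point
    iteration so the median *after* truncation to (lo, hi) hits the
    published median (asymmetric truncation otherwise shifts it).
    """
    sigma = max(np.log(hi / median), np.log(median / lo)) / _Z_RANGE
    sigma = max(sigma, 1e-6)
    mu = np.log(median)
    for _ in range(6):
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        z_med = stats.norm.ppf(0.5 * (stats.norm.cdf(a) + stats.norm.cdf(b)))
        mu_new = np.log(median) - sigma * z_med
        if abs(mu_new - mu) < 1e-12:
            mu = mu_new
            break
        mu = mu_new
    return mu, sigma


def _draw_truncated(rng, median, lo, hi, size=None, normal=None):
    """Truncated log-normal draw(s); `normal` supplies standard-normal input
    (for copula coupling), otherwise fresh rejection sampling is used."""
    mu, sigma = _lognormal_params(median, lo, hi)
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    if normal is not None:
        # map the copula normal through the truncated quantile function
        u = stats.norm.cdf(normal)
        z = stats.norm.ppf(stats.norm.cdf(a) + u * (stats.norm.cdf(b) - stats.norm.cdf(a)))
        return np.exp(mu + sigma * z)
    z = stats.truncnorm.rvs(a, b, size=size, random_state=rng)
    return np.exp(mu + sigma * z)


def generate_covariates(spec: CohortSpec, seed) -> List[CovariateVector]:
    """Sample one covariate vector per subject, arm by arm.

    Subjects violating the eligibility window (BMI, creatinine) are
    rejected and redrawn, so the returned cohort always satisfies the
    study's inclusion criteria.
    """
    rng = np.random.default_rng(seed)
    out: List[CovariateVector] = []
    for arm in ("NONE", "ECC", "MIECC"):
        n = spec.n_per_arm.get(arm, 0)
        table = spec.covariate_table[arm]
        n_m, n_f = spec.sex_counts[arm]
        sexes = np.array(["M"] * n_m + ["F"] * n_f)
        if len(sexes) != n:
            # arm size changed but sex counts not updated: keep the M/F ratio
            ratio = n_m / max(n_m + n_f, 1)
            n_m_adj = int(round(ratio * n))
            sexes = np.array(["M"] * n_m_adj + ["F"] * (n - n_m_adj))
        rng.shuffle(sexes)
        for sex in sexes:
            for _ in range(1000):
                zw, zh = stats.multivariate_normal.rvs(
                    mean=[0, 0],
                    cov=[[1, _WT_HT_COPULA_R], [_WT_HT_COPULA_R, 1]],
                    random_state=rng,
                )
                wt = float(_draw_truncated(rng, *table["WT"], normal=zw))
                ht = float(_draw_truncated(rng, *table["HT"], normal=zh))
                scr = float(_draw_truncated(rng, *table["SCR"]))
                age = float(_draw_truncated(rng, *table["AGE"]))
                bmi = wt / (ht / 100.0) ** 2
                if spec.bmi_bounds[0] <= bmi <= spec.bmi_bounds[1] and scr < spec.creatinine_max:
                    break
            else:  # pragma: no cover - would need a pathological spec
                raise RuntimeError(f"could not satisfy eligibility in arm {arm}")
            out.append(
                CovariateVector(
                    egfr=float(egfr_ckd_epi(scr, age, sex)),
                    bsa=float(bsa_dubois(wt, ht)),
                    support=arm,
                    sex=str(sex),
                    age=age,
                    weight=wt,
                    height=ht,
                    serum_creatinine=scr,
                    bilirubin=float(_draw_truncated(rng, *table["BILI"])),
                    albumin=float(_draw_truncated(rng, *table["ALB"])),
                    total_protein=float(_draw_truncated(rng, *table["TPROT"])),
                    urea=float(_draw_truncated(rng, *table["UREA"])),
                )
            )
    return out


def _covariate_row(cov: CovariateVector) -> dict:
    return {
        "ARM": cov.support, "SEX": cov.sex, "AGE": cov.age, "WT": cov.weight,
        "HT": cov.height, "SCR": cov.serum_creatinine, "BILI": cov.bilirubin,
        "ALB": cov.albumin, "TPROT": cov.total_protein, "UREA": cov.urea,
        "BSA": cov.bsa, "EGFR": cov.egfr,
    }


def generate_design(
    spec: CohortSpec, covariates: List[CovariateVector], seed
) -> PKDataset:
    """Dosing and planned sampling times: one 2 g bolus at t=0 per subject,
    the nominal schedule, and an end-of-surgery sample at
    (incision delay ~ U(30, 60)) + (arm-specific surgery duration)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, cov in enumerate(covariates, start=1):
        base = _covariate_row(cov)
        rows.append({"ID": i, "TIME": 0.0, "DV": np.nan, "AMT": spec.dose_mg,
                     "EVID": 1, "MDV": 1, "BLQ": 0, **base})
        delay = rng.uniform(*spec.incision_delay_min)
        duration = float(_draw_truncated(rng, *spec.surgery_duration[cov.support]))
        eos = delay + duration
        times = sorted(set(spec.nominal_times_min) | {round(eos, 1)})
        for t in times:
            rows.append({"ID": i, "TIME": float(t), "DV": np.nan, "AMT": np.nan,
                         "EVID": 0, "MDV": 1, "BLQ": 0, **base})
    return PKDataset(pd.DataFrame(rows, columns=ALL_COLUMNS))


def simulate_observations(
    m: PopulationModel, design: PKDataset, seed
) -> PKDataset:
    """Fill the observation slots of a design with simulated concentrations.

    Each subject gets random effects drawn from the model, the structural
    prediction at every planned time, and residual noise from the active
    error model (proportional by default: y = f·(1 + b·eps)).  Simulated
    values below zero are truncated at zero and flagged as below-limit.
    """
    rng = np.random.default_rng(seed)
    df = design.df.copy()
    for sid in design.subject_ids:
        cov = design.covariate_vector(sid)
        params = sample_individual(m, cov, rng)
        doses = design.dose_events(sid)
        mask = (df["ID"] == sid) & (df["EVID"] == 0)
        times = df.loc[mask, "TIME"].to_numpy()
        f = concentration(params, doses, times)
        eps = rng.standard_normal(times.size)
        y = f + m.error_sd(f) * eps
        blq = y < 0
        df.loc[mask, "DV"] = np.where(blq, 0.0, y)
        df.loc[mask, "BLQ"] = blq.astype(int)
        df.loc[mask, "MDV"] = 0
    return PKDataset(df)


def simulate_cohort(m: PopulationModel, spec: CohortSpec | None = None, seed=0) -> PKDataset:
    """Covariates + design + observations in one seeded call.

    The three stages consume deterministic sub-seeds of ``seed`` so the
    full dataset is reproducible.
    """
    spec = spec if spec is not None else CohortSpec()
    ss = np.random.SeedSequence(seed).spawn(3)
    covs = generate_covariates(spec, ss[0])
    design = generate_design(spec, covs, ss[1])
    return simulate_observations(m, design, ss[2])
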