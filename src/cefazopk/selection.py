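"""Covariate screening and stepwise covariate-model building.

The two-stage procedure used for the cefazolin model: first a univariate
Pearson screen of every candidate covariate against the empirical Bayes
eta of every parameter (point-biserial, i.e. Pearson against a 0/1
indicator, for sex and the support modality), keeping candidates with
p < 0.05; then forward stepwise inclusion, accepting at each round the
candidate with the largest drop in objective function value provided the
drop is at least 3.84 points (chi-square, 1 df, p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

from scipy import stats

from .dataset import PKDataset
from .model import (CATEGORICAL_COVARIATES, CONTINUOUS_COVARIATES,
                    PARAM_NAMES, PopulationModel)
from .estimate import FitResult, SAEMSettings, ofv, saem_fit

logger = logging.getLogger(__name__)

__all__ = ["CovariateCandidate", "covariate_screen", "stepwise_covariates",
           "OFV_THRESHOLD"]

#: chi-square 95th percentile, 1 df: the nested-model significance cutoff.
OFV_THRESHOLD = 3.84


@dataclass(frozen=True)
class CovariateCandidate:
    """A (parameter, covariate) pair surviving the univariate screen."""

    parameter: str
    covariate: str
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def covariate_screen(
    fit: FitResult,
    data: PKDataset,
    alpha: float = 0.05,
    covariates: Optional[Sequence[str]] = None,
) -> List[CovariateCandidate]:
    """Univariate Pearson screen of covariates against the EBE etas.

    Returns the candidates with p < ``alpha`` sorted by p-value.  Covariates
    already in the fitted model's covariate structure for a given parameter
    are not re-proposed for it.  Constant covariate columns are skipped.
    """
    covs = data.covariates()
    names = list(covariates) if covariates is not None else (
        list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_COVARIATES)
    )
    out: List[CovariateCandidate] = []
    for name in names:
        if name in ("ECC", "MIECC"):
            x = (covs["ARM"] == name).to_numpy(float)
        elif name == "SEX":
            x = (covs["SEX"] == "F").to_numpy(float)
        else:
            x = covs[name].to_numpy(float)
        if x.std() == 0:
            logger.warning("covariate %s is constant; skipped", name)
            continue
        for param in PARAM_NAMES:
            if name in fit.model.covariate_effects.get(param, {}):
                continue
            eta = fit.ebe[f"eta_{param}"].to_numpy(float)
            if eta.std() == 0:
                continue
            r, p = stats.pearsonr(x, eta)
            if p < alpha:
                out.append(CovariateCandidate(param, name, float(p)))
    return sorted(out, key=lambda c: c.p_value)


def _with_candidate(m: PopulationModel, cand: CovariateCandidate) -> PopulationModel:
    eff = {p: dict(v) for p, v in m.covariate_effects.items()}
    eff.setdefault(cand.parameter, {})[cand.covariate] = 0.0
    return replace(m, covariate_effects=eff)


def stepwise_covariates(
    data: PKDataset,
    base: PopulationModel,
    candidates: Sequence[CovariateCandidate],
    seed: int = 0,
    settings: Optional[SAEMSettings] = None,
    threshold: float = OFV_THRESHOLD,
    ofv_nmc: int = 1000,
) -> PopulationModel:
    """Forward stepwise covariate inclusion at a fixed OFV threshold.

    Every remaining candidate is fitted on top of the current model with
    SAEM; the largest OFV drop wins the round if it is at least
    ``threshold``, otherwise selection stops.  OFV values for competing
    models within a round share the same Monte Carlo seed, so only
    genuine likelihood differences separate them.

    Returns the final model (the refitted current model with all accepted
    covariates); with no candidates the base model is returned unchanged.
    """
    if not candidates:
        return base
    st = settings or SAEMSettings(compute_rse=False)
    current = base
    current_fit = saem_fit(data, current, st, seed=seed)
    current_ofv = ofv(current_fit.model, data, nmc=ofv_nmc, seed=seed,
                     ebe_df=current_fit.ebe)
    current = current_fit.model
    remaining = list(candidates)
    round_no = 0
    while remaining:
        round_no += 1
        best = None
        for cand in remaining:
            try:
                fit = saem_fit(data, _with_candidate(current, cand), st, seed=seed)
                val = ofv(fit.model, data, nmc=ofv_nmc, seed=seed, ebe_df=fit.ebe)
            except Exception:  # noqa: BLE001 - a failed candidate fit is skipped
                logger.exception("candidate %s on %s failed; excluded this round",
                                 cand.covariate, cand.parameter)
                continue
            if best is None or val < best[1]:
                best = (cand, val, fit.model)
        if best is None:
            break
        cand, val, mdl = best
        drop = current_ofv - val
        logger.info("stepwise round %d: best candidate %s on %s, dOFV=%.2f",
                    round_no, cand.covariate, cand.parameter, drop)
        if drop >= threshold:
            current, current_ofv = mdl, val
            remaining = [c for c in remaining
                         if (c.parameter, c.covariate) != (cand.parameter, cand.covariate)]
        else:
            break
    return current
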