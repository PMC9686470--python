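"""Nonparametric bootstrap of the population fit.

Subjects are resampled with replacement, stratified by support arm so
every replicate keeps the study's arm structure, and the model is
refitted on each replicate.  Percentile medians and 95% CIs summarize
the parameter uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .dataset import PKDataset
from .estimate import SAEMSettings, parameter_vector, saem_fit
from .model import PopulationModel

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "bootstrap"]


@dataclass
class BootstrapResult:
    """Percentile summary plus the per-replicate estimates and resample indices."""

    summary: pd.DataFrame          # parameter, median, ci_lower, ci_upper
    replicates: pd.DataFrame       # one row per successful refit
    indices: np.ndarray            # (n_boot, n_subjects) resampled subject ids
    n_failed: int

    def ci(self, parameter: str) -> tuple:
        row = self.summary.set_index("parameter").loc[parameter]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _resample_ids(data: PKDataset, rng) -> np.ndarray:
    covs = data.covariates()
    picked = []
    for arm in covs["ARM"].unique():
        ids = covs.index[covs["ARM"] == arm].to_numpy()
        picked.append(rng.choice(ids, size=len(ids), replace=True))
    return np.concatenate(picked)


def _rebuild(data: PKDataset, ids: np.ndarray) -> PKDataset:
    frames = []
    for new_id, sid in enumerate(ids, start=1):
        g = data.df[data.df["ID"] == sid].copy()
        g["ID"] = new_id
        frames.append(g)
    return PKDataset(pd.concat(frames, ignore_index=True))


def bootstrap(
    data: PKDataset,
    m: PopulationModel,
    n_boot: int = 500,
    seed: int = 0,
    settings: Optional[SAEMSettings] = None,
    identity_resampling: bool = False,
) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the SAEM fit.

    ``m`` provides both the model structure and the starting values for
    every refit.  Failed refits are dropped and counted; more than 20%
    failures triggers a warning.  ``identity_resampling=True`` replaces the
    resampling by the original dataset (every replicate identical), which
    is the degenerate check that medians equal point estimates.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    st = settings or SAEMSettings(compute_rse=False)
    rng = np.random.default_rng(seed)
    all_ids = data.covariates().index.to_numpy()
    index_sets = []
    rows = []
    n_failed = 0
    if identity_resampling:
        # every replicate is the original data under the same seed: one
        # deterministic fit, replicated, so medians equal point estimates
        fit = saem_fit(data, m, st, seed=seed)
        rows = [parameter_vector(fit.model)] * n_boot
        index_sets = [all_ids.copy() for _ in range(n_boot)]
    else:
        for b in range(n_boot):
            ids = _resample_ids(data, rng)
            index_sets.append(ids)
            try:
                rep = _rebuild(data, ids)
                fit = saem_fit(rep, m, st, seed=int(rng.integers(2**31 - 1)))
                rows.append(parameter_vector(fit.model))
            except Exception:  # noqa: BLE001
                logger.exception("bootstrap replicate %d failed", b)
                n_failed += 1
    if n_failed > 0.2 * n_boot:
        logger.warning("%d of %d bootstrap refits failed", n_failed, n_boot)
    reps = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "parameter": reps.columns,
        "median": reps.median().to_numpy(),
        "ci_lower": reps.quantile(0.025).to_numpy(),
        "ci_upper": reps.quantile(0.975).to_numpy(),
    })
    return BootstrapResult(
        summary=summary, replicates=reps,
        indices=np.array(index_sets), n_failed=n_failed,
    )
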