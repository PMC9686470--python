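"""Goodness-of-fit diagnostics: weighted residuals, NPDE and the VPC.

All simulation-based diagnostics share one reference: ``nsim`` full
replicates of the dataset at the original design points (same subjects,
covariates and times) with fresh random effects and residual noise.

* IWRES — individual weighted residual, ``(y - f_ind) / sd(f_ind)`` with
  the individual prediction from the EBEs and the active error model's SD
  (``sqrt(a² + (b f)²)`` in the combined case).
* PWRES — population weighted residual: per subject, the observation
  vector decorrelated by the Cholesky factor of the empirical simulation
  covariance, ``L⁻¹(y - E_sim)``.
* NPDE — normalized prediction distribution error: the rank of each
  decorrelated observation among its decorrelated simulations, mapped
  through the normal quantile function; a half-offset rank keeps the
  result finite at the extremes.  Under the true model NPDE ~ N(0, 1).
* VPC — observed 10/50/90th percentiles per time bin against the
  simulated 90% CI of the same percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PKDataset
from .estimate import FitResult, _Cohort, _log_tv_matrix, _predict_phi, ebes
from .model import PARAM_NAMES, PopulationModel

logger = logging.getLogger(__name__)

__all__ = ["ResidualTable", "VPCBands", "simulate_reference", "residuals", "vpc"]


@dataclass
class ResidualTable:
    """Per-observation predictions and residual diagnostics."""

    table: pd.DataFrame  # ID, TIME, DV, PRED, IPRED, PWRES, IWRES, NPDE


@dataclass
class VPCBands:
    """Observed percentiles and simulated percentile CIs per time bin."""

    table: pd.DataFrame  # bin_mid, bin_lo, bin_hi, n_obs, then per percentile:
    #                      obs_pXX, sim_pXX_lo, sim_pXX_hi
    percentiles: Sequence[float]


def simulate_reference(
    m: PopulationModel, data: PKDataset, nsim: int = 1000, seed: int = 0
) -> np.ndarray:
    """``nsim`` replicates of the dataset at its own design points.

    Returns an array of shape (nsim, n_observations) ordered like
    ``data.observations()``.  Each replicate draws new etas per subject
    and new residual noise.
    """
    if nsim < 1:
        raise ValueError("nsim must be positive")
    rng = np.random.default_rng(seed)
    cohort = _Cohort(data)
    log_tv = _log_tv_matrix(m, cohort)
    omega = np.array([m.omega.get(p, 0.0) for p in PARAM_NAMES])
    out = np.empty((nsim, cohort.n_obs))
    for r in range(nsim):
        eta = omega * rng.standard_normal((cohort.n, 4))
        f = _predict_phi(log_tv + eta, cohort)
        y = f + m.error_sd(f) * rng.standard_normal(f.shape)
        out[r] = np.maximum(y[cohort.mask], 0.0)
    return out


def residuals(
    m: PopulationModel,
    data: PKDataset,
    ref: np.ndarray,
    fit: Optional[FitResult] = None,
    ridge: float = 1e-8,
) -> ResidualTable:
    """PWRES, IWRES and NPDE for every observation.

    ``ref`` is the simulation matrix from :func:`simulate_reference`.
    Individual predictions use the EBEs of ``fit`` when given, otherwise
    they are recomputed from the data.
    """
    cohort = _Cohort(data)
    log_tv = _log_tv_matrix(m, cohort)
    ebe_df = fit.ebe if fit is not None else ebes(m, data)
    eta_hat = ebe_df[[f"eta_{p}" for p in PARAM_NAMES]].to_numpy(float)

    f_ind = _predict_phi(log_tv + eta_hat, cohort)
    f_pop = _predict_phi(log_tv, cohort)
    nsim = ref.shape[0]

    obs = data.observations().reset_index(drop=True)
    y_all = cohort.y[cohort.mask]
    # slice bounds of each subject in the flattened observation ordering
    counts = cohort.mask.sum(axis=1)
    stops = np.cumsum(counts)
    starts = stops - counts

    pwres = np.empty_like(y_all)
    npde = np.empty_like(y_all)
    for i in range(cohort.n):
        sl = slice(starts[i], stops[i])
        sims = ref[:, sl]                        # (nsim, k)
        mu = sims.mean(axis=0)
        cov = np.cov(sims, rowvar=False)
        cov = np.atleast_2d(cov) + ridge * np.eye(counts[i])
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            logger.info("singular simulation covariance for subject %s; "
                        "ridge increased", cohort.ids[i])
            L = np.linalg.cholesky(cov + 1e-4 * np.trace(cov) / counts[i] * np.eye(counts[i]))
        y_dec = np.linalg.solve(L, y_all[sl] - mu)
        pwres[sl] = y_dec
        sims_dec = np.linalg.solve(L, (sims - mu).T).T
        rank = (sims_dec < y_dec).sum(axis=0)
        pde = (rank + 0.5) / (nsim + 1.0)
        npde[sl] = stats.norm.ppf(pde)

    iw_sd = np.maximum(m.error_sd(f_ind[cohort.mask]), 1e-12)
    iwres = (y_all - f_ind[cohort.mask]) / iw_sd

    table = pd.DataFrame({
        "ID": obs["ID"], "TIME": obs["TIME"], "DV": obs["DV"],
        "PRED": f_pop[cohort.mask], "IPRED": f_ind[cohort.mask],
        "PWRES": pwres, "IWRES": iwres, "NPDE": npde,
    })
    return ResidualTable(table)


def _default_bins(times: np.ndarray, nominal: Sequence[float]) -> List[tuple]:
    """Nominal-time bins plus quantile bins for the late (end-of-surgery) times."""
    nominal = sorted(nominal)
    edges = [0.0]
    for a, b in zip(nominal[:-1], nominal[1:]):
        edges.append(0.5 * (a + b))
    edges.append(nominal[-1] + 0.5 * (nominal[-1] - nominal[-2]))
    late = times[times > edges[-1]]
    if late.size:
        qs = np.quantile(late, [0.5]) if late.size >= 10 else []
        edges.extend(sorted(qs))
        edges.append(float(times.max()) + 1.0)
    return list(zip(edges[:-1], edges[1:]))


def vpc(
    m: PopulationModel,
    data: PKDataset,
    nsim: int = 1000,
    bins: Optional[Sequence[tuple]] = None,
    seed: int = 0,
    percentiles: Sequence[float] = (10.0, 50.0, 90.0),
    ci_level: float = 90.0,
    ref: Optional[np.ndarray] = None,
    min_bin_size: int = 5,
) -> VPCBands:
    """Visual predictive check.

    Observed percentiles (default 10/50/90) per time bin, with the
    ``ci_level``% interval of the same percentile across ``nsim``
    simulated replicates.  Bins default to the nominal sampling times
    plus a split of the end-of-surgery tail; bins with fewer than
    ``min_bin_size`` observations are merged with their neighbor.
    """
    obs = data.observations().reset_index(drop=True)
    times = obs["TIME"].to_numpy(float)
    y = obs["DV"].to_numpy(float)
    if ref is None:
        ref = simulate_reference(m, data, nsim=nsim, seed=seed)
    if bins is None:
        nominal = sorted(set(np.round(times[times <= 180], 0)))[:6] or [times.min()]
        # use the canonical schedule when present in the data
        sched = [t for t in (15.0, 30.0, 45.0, 60.0, 120.0, 180.0)
                 if np.any(np.isclose(times, t))]
        bins = _default_bins(times, sched or nominal)
    bins = list(bins)
    # merge undersized bins
    merged = True
    while merged and len(bins) > 1:
        merged = False
        for i, (lo, hi) in enumerate(bins):
            n_in = int(((times >= lo) & (times < hi)).sum())
            if n_in < min_bin_size:
                j = i + 1 if i + 1 < len(bins) else i - 1
                lo2, hi2 = bins[j]
                newbin = (min(lo, lo2), max(hi, hi2))
                bins = [b for k, b in enumerate(bins) if k not in (i, j)]
                bins.append(newbin)
                bins.sort()
                logger.info("VPC bin [%g, %g) merged (only %d obs)", lo, hi, n_in)
                merged = True
                break

    lo_q = (100.0 - ci_level) / 2.0
    hi_q = 100.0 - lo_q
    rows = []
    for lo, hi in bins:
        sel = (times >= lo) & (times < hi)
        if not sel.any():
            continue
        row = {
            "bin_lo": lo, "bin_hi": hi,
            "bin_mid": float(np.median(times[sel])), "n_obs": int(sel.sum()),
        }
        for p in percentiles:
            row[f"obs_p{p:g}"] = float(np.percentile(y[sel], p))
            sim_p = np.percentile(ref[:, sel], p, axis=1)
            row[f"sim_p{p:g}_lo"] = float(np.percentile(sim_p, lo_q))
            row[f"sim_p{p:g}_med"] = float(np.percentile(sim_p, 50.0))
            row[f"sim_p{p:g}_hi"] = float(np.percentile(sim_p, hi_q))
        rows.append(row)
    return VPCBands(pd.DataFrame(rows), percentiles)


# ---------------------------------------------------------------------------
# plotting payloads
# ---------------------------------------------------------------------------


def gof_plots(res: ResidualTable, path):
    """Observed-vs-predicted and residual-vs-time/prediction panels (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = res.table
    fig, axes = plt.subplots(2, 3, figsize=(13, 8))
    for ax, (x, yv, xl, yl) in zip(axes.flat, [
        (t["PRED"], t["DV"], "population prediction (mg/L)", "observed (mg/L)"),
        (t["IPRED"], t["DV"], "individual prediction (mg/L)", "observed (mg/L)"),
        (t["TIME"], t["PWRES"], "time (min)", "PWRES"),
        (t["TIME"], t["IWRES"], "time (min)", "IWRES"),
        (t["TIME"], t["NPDE"], "time (min)", "NPDE"),
        (t["PRED"], t["NPDE"], "population prediction (mg/L)", "NPDE"),
    ]):
        ax.scatter(x, yv, s=8, alpha=0.6)
        if yl in ("PWRES", "IWRES", "NPDE"):
            ax.axhline(0.0, color="k", lw=0.8)
        else:
            lim = [0, max(x.max(), yv.max()) * 1.05]
            ax.plot(lim, lim, "k-", lw=0.8)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vpc_plot(bands: VPCBands, data: PKDataset, path):
    """VPC figure: observed percentiles over the simulated CI ribbons."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = data.observations()
    fig, ax = plt.subplots(figsize=(8, 5))
    t = bands.table
    colors = {10: "#9ecae1", 50: "#fcb9b2", 90: "#9ecae1"}
    for p in bands.percentiles:
        ax.fill_between(t["bin_mid"], t[f"sim_p{p:g}_lo"], t[f"sim_p{p:g}_hi"],
                        alpha=0.5, color=colors.get(int(p), "#cccccc"),
                        label=f"simulated {p:g}th percentile CI")
        ax.plot(t["bin_mid"], t[f"obs_p{p:g}"], "b-", lw=1.5)
    ax.scatter(obs["TIME"], obs["DV"], s=8, color="k", alpha=0.35, zorder=3)
    ax.set_xlabel("time after dose (min)")
    ax.set_ylabel("cefazolin concentration (mg/L)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
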