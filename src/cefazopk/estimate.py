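"""Population estimation by SAEM, objective function, EBEs and standard errors.

The Stochastic Approximation Expectation-Maximization (SAEM) algorithm
alternates a Markov-chain E-step — Metropolis-Hastings sampling of each
subject's log-scale random effects given the current population
parameters — with a stochastic-approximation M-step that updates fixed
effects, random-effect SDs and residual-error parameters from smoothed
sufficient statistics.  An exploratory phase (step size 1, simulated
annealing on the variance parameters) precedes a smoothing phase with
step size k^-0.7, after which the parameter path averages out the Monte
Carlo noise.

The objective function value (OFV, -2 log marginal likelihood) is
estimated by importance sampling around the empirical Bayes estimates
with a heavy-tailed multivariate-t proposal; standard errors come from a
linearized (first-order conditional) Fisher information matrix, which is
deterministic given the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special

from .dataset import PKDataset
from .model import PARAM_NAMES, PopulationModel

logger = logging.getLogger(__name__)

__all__ = [
    "SAEMSettings", "FitResult", "saem_fit", "ofv", "ebes",
    "standard_errors", "initial_model", "parameter_table", "parameter_vector",
]

_SD_FLOOR = 1e-10
# omega is floored at 0.01 during estimation: below this the random-effect
# prior pins the individual parameters to the typical values and the chain
# can no longer track the data; a parameter truly without variability
# should be dropped from the iiv set instead (the fit then degenerates to
# deterministic weighted least squares, handled explicitly).
_OMEGA2_FLOOR = 1e-4


@dataclass
class SAEMSettings:
    """Tuning of the SAEM run.

    150 exploratory + 350 smoothing iterations with 5 MCMC transitions per
    subject per iteration; the random-walk proposal is adapted toward a
    0.3-0.5 acceptance rate, and simulated annealing (geometric floor,
    rate 0.95) keeps the variance parameters from collapsing during
    exploration.  The smoothing phase is deliberately long relative to
    exploration because the weakly identified peripheral parameters
    otherwise random-walk during the unit-step phase.
    """

    n_exploration: int = 150
    n_smoothing: int = 350
    n_mcmc: int = 5
    step_exponent: float = 0.7
    exploration_step: float = 1.0
    annealing_rate: float = 0.95
    iiv: Tuple[str, ...] = PARAM_NAMES
    estimate_error: bool = True
    estimate_omega: bool = True
    compute_rse: bool = True
    convergence_window: int = 40
    convergence_rtol: float = 0.15


@dataclass
class FitResult:
    """SAEM output: estimates, precision, EBEs and the iteration path."""

    model: PopulationModel
    rse_percent: Optional[Dict[str, float]]
    ofv: Optional[float]
    ebe: pd.DataFrame
    trace: pd.DataFrame
    converged: bool
    seed: int
    settings: SAEMSettings


# ---------------------------------------------------------------------------
# vectorized data layout
# ---------------------------------------------------------------------------


class _Cohort:
    """Padded array layout of a PKDataset for vectorized likelihoods."""

    def __init__(self, data: PKDataset):
        self.ids = list(data.subject_ids)
        self.n = len(self.ids)
        obs = data.observations()
        grouped = {sid: g for sid, g in obs.groupby("ID", sort=False)}
        tmax = max(len(g) for g in grouped.values())
        self.times = np.zeros((self.n, tmax))
        self.y = np.zeros((self.n, tmax))
        self.mask = np.zeros((self.n, tmax), dtype=bool)
        for i, sid in enumerate(self.ids):
            g = grouped[sid]
            k = len(g)
            self.times[i, :k] = g["TIME"].to_numpy()
            self.y[i, :k] = g["DV"].to_numpy()
            self.mask[i, :k] = g["MDV"].to_numpy() == 0
        doses = data.doses()
        dmax = doses.groupby("ID").size().max()
        self.dose_t = np.full((self.n, dmax), np.nan)
        self.dose_a = np.zeros((self.n, dmax))
        for i, sid in enumerate(self.ids):
            g = doses[doses["ID"] == sid]
            self.dose_t[i, : len(g)] = g["TIME"].to_numpy()
            self.dose_a[i, : len(g)] = g["AMT"].to_numpy()
        covs = data.covariates()
        self.cov_frame = covs
        # numeric covariate matrix per parameter is built lazily per model
        self.n_obs = int(self.mask.sum())

    def covariate_matrix(self, m: PopulationModel, param: str) -> Tuple[np.ndarray, List[str]]:
        names = sorted(m.covariate_effects.get(param, {}))
        cols = []
        for name in names:
            if name in ("ECC", "MIECC"):
                x = (self.cov_frame["ARM"] == name).to_numpy(float)
            elif name == "SEX":
                x = (self.cov_frame["SEX"] == "F").to_numpy(float)
            elif name == "EGFR":
                x = self.cov_frame["EGFR"].to_numpy(float) * m.egfr_unit_scale
            else:
                x = self.cov_frame[name].to_numpy(float)
            cols.append(x)
        X = np.column_stack(cols) if cols else np.zeros((self.n, 0))
        return X, names


def _conc_matrix(cl, v1, q, v2, cohort: _Cohort, times=None) -> np.ndarray:
    """Closed-form concentrations for all subjects at the padded time grid."""
    times = cohort.times if times is None else times
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    al = 0.5 * (s + disc)
    be = 0.5 * (s - disc)
    spread = np.maximum(al - be, 1e-12)
    a_coef = (al - k21) / (v1 * spread)
    b_coef = (k21 - be) / (v1 * spread)
    out = np.zeros_like(times)
    for j in range(cohort.dose_t.shape[1]):
        dt = (times - cohort.dose_t[:, j, None]) / 60.0
        ok = (dt >= 0) & np.isfinite(dt)
        dt = np.where(ok, dt, 0.0)
        resp = cohort.dose_a[:, j, None] * (
            a_coef[:, None] * np.exp(-al[:, None] * dt)
            + b_coef[:, None] * np.exp(-be[:, None] * dt)
        )
        out += np.where(ok, resp, 0.0)
    return out


def _predict_phi(phi: np.ndarray, cohort: _Cohort, times=None) -> np.ndarray:
    p = np.exp(phi)
    return _conc_matrix(p[:, 0], p[:, 1], p[:, 2], p[:, 3], cohort, times)


def _data_loglik(phi: np.ndarray, m: PopulationModel, cohort: _Cohort) -> np.ndarray:
    """Per-subject log p(y | phi)."""
    f = _predict_phi(phi, cohort)
    sd = np.maximum(m.error_sd(f), _SD_FLOOR)
    resid = (cohort.y - f) / sd
    ll = -0.5 * resid**2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
    return np.where(cohort.mask, ll, 0.0).sum(axis=1)


def _log_tv_matrix(m: PopulationModel, cohort: _Cohort) -> np.ndarray:
    """log typical value per subject per parameter, (n, 4)."""
    out = np.zeros((cohort.n, 4))
    for k, pname in enumerate(PARAM_NAMES):
        X, names = cohort.covariate_matrix(m, pname)
        beta = np.array([m.covariate_effects[pname][n] for n in names]) if names else np.zeros(0)
        term = X @ beta if names else np.zeros(cohort.n)
        pop = m.pop_value(pname)
        if m.covariate_mode == "natural_additive":
            tv = pop + term
            if np.any(tv <= 0):
                raise ValueError(
                    f"non-positive natural-additive typical value for {pname}"
                )
            out[:, k] = np.log(tv)
        else:
            out[:, k] = np.log(pop) + term
    return out


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------


def _fit_fixed_effects(
    m: PopulationModel, cohort: _Cohort, s1: np.ndarray
) -> PopulationModel:
    """M-step for the fixed effects: per-parameter least squares of the
    smoothed log individual parameters on the covariate model."""
    new_pop = {}
    new_effects = {p: dict(v) for p, v in m.covariate_effects.items()}
    for k, pname in enumerate(PARAM_NAMES):
        target = s1[:, k]
        X, names = cohort.covariate_matrix(m, pname)
        if not names:
            new_pop[pname] = float(np.exp(target.mean()))
            continue
        if m.covariate_mode == "log_linear":
            A = np.column_stack([np.ones(cohort.n), X])
            coef, *_ = np.linalg.lstsq(A, target, rcond=None)
            new_pop[pname] = float(np.exp(coef[0]))
            for j, nm in enumerate(names):
                new_effects[pname][nm] = float(coef[1 + j])
        else:
            x0 = np.concatenate(
                [[max(m.pop_value(pname), 1e-6)],
                 [m.covariate_effects[pname][nm] for nm in names]]
            )

            def resid(v):
                tv = np.maximum(v[0] + X @ v[1:], 1e-10)
                return target - np.log(tv)

            scale = max(float(np.exp(target.mean())), 1e-6)
            lower = np.concatenate([[1e-8], np.full(len(names), -np.inf)])
            upper = np.full(1 + len(names), np.inf)
            best = None
            # the intercept/slope surface can be multimodal when the
            # covariate never approaches zero; a couple of restarts around
            # the data scale keeps the update out of boundary traps
            starts = [x0, np.concatenate([[scale], np.zeros(len(names))])]
            for s0 in starts:
                sol = optimize.least_squares(
                    resid, np.clip(s0, lower, upper), bounds=(lower, upper),
                    method="trf", max_nfev=200,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
            new_pop[pname] = float(best.x[0])
            for j, nm in enumerate(names):
                new_effects[pname][nm] = float(best.x[1 + j])
    return replace(m.with_pop_values(**new_pop), covariate_effects=new_effects)


def saem_fit(
    data: PKDataset,
    m0: PopulationModel,
    settings: Optional[SAEMSettings] = None,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood population fit by SAEM.

    Parameters
    ----------
    data : PKDataset
        Long-format dose + observation records.
    m0 : PopulationModel
        Initial values; its covariate structure defines which coefficients
        are estimated.
    settings : SAEMSettings, optional
    seed : int
        Seed for the MCMC chains; identical seeds give identical traces.
    """
    st = settings or SAEMSettings()
    rng = np.random.default_rng(seed)
    cohort = _Cohort(data)
    m = m0
    iiv_idx = [k for k, p in enumerate(PARAM_NAMES) if p in st.iiv]
    fixed_idx = [k for k in range(4) if k not in iiv_idx]
    if not iiv_idx:
        return _fit_no_iiv(data, cohort, m, st, seed)

    log_tv = _log_tv_matrix(m, cohort)
    phi = log_tv.copy()
    ll = _data_loglik(phi, m, cohort)

    # stochastic-approximation state
    s1 = phi.copy()
    s2 = phi**2
    f0 = _predict_phi(phi, cohort)
    stat_prop = (((cohort.y - f0) / np.maximum(np.abs(f0), _SD_FLOOR)) ** 2)
    stat_add = (cohort.y - f0) ** 2
    stat_f = np.abs(f0)

    rw_scale = np.full(4, 0.4)
    trace_rows = []
    n_iter = st.n_exploration + st.n_smoothing

    omega2 = np.array([max(m.omega.get(p, 0.0) ** 2, _OMEGA2_FLOOR) for p in PARAM_NAMES])
    err_a2 = max(m.error_a, 1e-3 if m.error_model != "proportional" else 0.0) ** 2
    err_b2 = max(m.error_b, 1e-3 if m.error_model != "additive" else 0.0) ** 2

    for it in range(n_iter):
        gamma = (
            st.exploration_step
            if it < st.n_exploration
            else (it - st.n_exploration + 1) ** (-st.step_exponent)
        )
        omega = np.sqrt(omega2)

        # --- E-step: MCMC on phi -------------------------------------
        acc_counts = np.zeros(4)
        phi_states = []
        for _ in range(st.n_mcmc):
            if iiv_idx:
                # kernel 1: independent proposal from the prior
                phi_prop = phi.copy()
                phi_prop[:, iiv_idx] = (
                    log_tv[:, iiv_idx]
                    + omega[iiv_idx] * rng.standard_normal((cohort.n, len(iiv_idx)))
                )
                ll_prop = _data_loglik(phi_prop, m, cohort)
                accept = np.log(rng.uniform(size=cohort.n)) < (ll_prop - ll)
                phi[accept] = phi_prop[accept]
                ll[accept] = ll_prop[accept]
                # kernel 1b: component-wise independent proposal from the
                # prior (the joint proposal above is vetoed by the
                # well-identified components, so weakly informed ones need
                # their own refresh move to mix across the full prior)
                for c in iiv_idx:
                    phi_prop = phi.copy()
                    phi_prop[:, c] = log_tv[:, c] + omega[c] * rng.standard_normal(cohort.n)
                    ll_prop = _data_loglik(phi_prop, m, cohort)
                    accept = np.log(rng.uniform(size=cohort.n)) < (ll_prop - ll)
                    phi[accept] = phi_prop[accept]
                    ll[accept] = ll_prop[accept]
                # kernel 2: component-wise random walk
                for c in iiv_idx:
                    phi_prop = phi.copy()
                    phi_prop[:, c] = phi[:, c] + rw_scale[c] * omega[c] * rng.standard_normal(cohort.n)
                    ll_prop = _data_loglik(phi_prop, m, cohort)
                    dprior = (
                        (phi[:, c] - log_tv[:, c]) ** 2
                        - (phi_prop[:, c] - log_tv[:, c]) ** 2
                    ) / (2 * omega2[c])
                    accept = np.log(rng.uniform(size=cohort.n)) < (ll_prop - ll + dprior)
                    phi[accept] = phi_prop[accept]
                    ll[accept] = ll_prop[accept]
                    acc_counts[c] += accept.mean()
            phi_states.append(phi.copy())
        # adapt random-walk scales toward 0.3-0.5 acceptance
        if st.n_mcmc and iiv_idx:
            rates = acc_counts / st.n_mcmc
            for c in iiv_idx:
                if rates[c] < 0.3:
                    rw_scale[c] *= 0.8
                elif rates[c] > 0.5:
                    rw_scale[c] *= 1.25
            rw_scale = np.clip(rw_scale, 1e-3, 50.0)

        # --- stochastic approximation of sufficient statistics --------
        # all chain states of the iteration enter the statistics, which
        # damps the per-iteration Monte Carlo noise of the M-step
        states = phi_states if phi_states else [phi]
        phi_bar = np.mean(states, axis=0)
        phi2_bar = np.mean([s**2 for s in states], axis=0)
        prop_bar = np.zeros_like(stat_prop)
        add_bar = np.zeros_like(stat_add)
        f_bar = np.zeros_like(stat_f)
        for s in states:
            f = _predict_phi(s, cohort)
            fa = np.maximum(np.abs(f), _SD_FLOOR)
            prop_bar += ((cohort.y - f) / fa) ** 2
            add_bar += (cohort.y - f) ** 2
            f_bar += fa
        prop_bar /= len(states)
        add_bar /= len(states)
        f_bar /= len(states)
        s1 = (1 - gamma) * s1 + gamma * phi_bar
        s2 = (1 - gamma) * s2 + gamma * phi2_bar
        stat_prop = (1 - gamma) * stat_prop + gamma * prop_bar
        stat_add = (1 - gamma) * stat_add + gamma * add_bar
        stat_f = (1 - gamma) * stat_f + gamma * f_bar

        # --- M-step ---------------------------------------------------
        m = _fit_fixed_effects(m, cohort, s1)
        log_tv = _log_tv_matrix(m, cohort)
        if fixed_idx:
            phi[:, fixed_idx] = log_tv[:, fixed_idx]
        if st.estimate_omega:
            om_new = np.maximum(
                (s2 - 2 * s1 * log_tv + log_tv**2).mean(axis=0), _OMEGA2_FLOOR
            )
            if it < st.n_exploration:
                om_new = np.maximum(om_new, st.annealing_rate * omega2)
            omega2[iiv_idx] = om_new[iiv_idx]
        if st.estimate_error:
            msk = cohort.mask
            if m.error_model == "proportional":
                b2 = float(stat_prop[msk].mean())
                if it < st.n_exploration:
                    b2 = max(b2, st.annealing_rate * err_b2)
                err_b2 = max(b2, 1e-12)
            elif m.error_model == "additive":
                a2 = float(stat_add[msk].mean())
                if it < st.n_exploration:
                    a2 = max(a2, st.annealing_rate * err_a2)
                err_a2 = max(a2, 1e-12)
            else:
                r2 = stat_add[msk]
                fm = stat_f[msk]

                def nll(v):
                    var = np.exp(2 * v[0]) + np.exp(2 * v[1]) * fm**2
                    return float(np.sum(np.log(var) + r2 / var))

                v0 = 0.5 * np.log([max(err_a2, 1e-8), max(err_b2, 1e-8)])
                sol = optimize.minimize(nll, v0, method="Nelder-Mead")
                a2_new, b2_new = np.exp(2 * sol.x)
                if it < st.n_exploration:
                    a2_new = max(a2_new, st.annealing_rate * err_a2)
                    b2_new = max(b2_new, st.annealing_rate * err_b2)
                err_a2, err_b2 = max(a2_new, 1e-12), max(b2_new, 1e-12)

        m = replace(
            m,
            omega={p: float(np.sqrt(omega2[k])) for k, p in enumerate(PARAM_NAMES)},
            error_a=float(np.sqrt(err_a2)) if m.error_model != "proportional" else m.error_a,
            error_b=float(np.sqrt(err_b2)) if m.error_model != "additive" else m.error_b,
        )
        ll = _data_loglik(phi, m, cohort)
        trace_rows.append(parameter_vector(m))

    trace = pd.DataFrame(trace_rows)
    converged = _trace_converged(trace, st)
    eta = phi - log_tv
    ebe_df = pd.DataFrame(eta, columns=[f"eta_{p}" for p in PARAM_NAMES])
    ebe_df.insert(0, "ID", cohort.ids)
    # replace the MCMC state with posterior modes for reporting
    ebe_df = _posterior_modes(m, cohort, ebe_df, iiv_idx)

    rse = None
    if st.compute_rse:
        try:
            rse = standard_errors(m, data, ebe_df, iiv=st.iiv)
        except np.linalg.LinAlgError:  # pragma: no cover
            logger.warning("Fisher information singular; RSEs unavailable")

    return FitResult(
        model=m, rse_percent=rse, ofv=None, ebe=ebe_df, trace=trace,
        converged=converged, seed=seed, settings=st,
    )


def _fit_no_iiv(
    data: PKDataset, cohort: _Cohort, m0: PopulationModel,
    st: SAEMSettings, seed: int,
) -> FitResult:
    """Degenerate fit without random effects: iterated weighted least squares.

    With an empty iiv set the marginal likelihood is an ordinary nonlinear
    regression, so the fixed effects are solved deterministically and the
    error parameters re-estimated from the residuals until stable.
    """
    m = m0
    names = [n for n in parameter_vector(m)
             if n.endswith("_pop") or n.startswith("beta_")]
    trace_rows = []

    def unpack(x):
        mm = m
        for nm, v in zip(names, x):
            val = float(np.exp(v)) if nm.endswith("_pop") else float(v)
            mm = _set_parameter(mm, nm, val)
        return mm

    x = np.array([
        np.log(parameter_vector(m)[nm]) if nm.endswith("_pop")
        else parameter_vector(m)[nm]
        for nm in names
    ])
    for _round in range(8):
        sd = None

        def resid(xv):
            mm = unpack(xv)
            try:
                f = _predict_phi(_log_tv_matrix(mm, cohort), cohort)
            except ValueError:
                # non-positive typical value along the search path
                return np.full(cohort.n_obs, 1e8)
            w = np.maximum(mm.error_sd(f), _SD_FLOOR)
            return ((cohort.y - f) / w)[cohort.mask]

        sol = optimize.least_squares(resid, x, method="trf", max_nfev=2000,
                                     x_scale="jac", ftol=1e-14, xtol=1e-14,
                                     gtol=1e-14)
        x = sol.x
        m = unpack(x)
        f = _predict_phi(_log_tv_matrix(m, cohort), cohort)
        if st.estimate_error:
            y, fm = cohort.y[cohort.mask], f[cohort.mask]
            fa = np.maximum(np.abs(fm), _SD_FLOOR)
            if m.error_model == "proportional":
                m = replace(m, error_b=float(np.sqrt(np.mean(((y - fm) / fa) ** 2))))
            elif m.error_model == "additive":
                m = replace(m, error_a=float(np.sqrt(np.mean((y - fm) ** 2))))
            else:
                r2 = (y - fm) ** 2

                def nll(v):
                    var = np.exp(2 * v[0]) + np.exp(2 * v[1]) * fa**2
                    return float(np.sum(np.log(var) + r2 / var))

                v0 = np.log([max(m.error_a, 1e-6), max(m.error_b, 1e-6)])
                best = optimize.minimize(nll, v0, method="Nelder-Mead")
                m = replace(m, error_a=float(np.exp(best.x[0])),
                            error_b=float(np.exp(best.x[1])))
        trace_rows.append(parameter_vector(m))
        if len(trace_rows) > 1:
            prev, cur = trace_rows[-2], trace_rows[-1]
            if all(abs(cur[k] - prev[k]) <= 1e-10 + 1e-8 * abs(prev[k]) for k in cur):
                break
    ebe_df = pd.DataFrame(np.zeros((cohort.n, 4)),
                          columns=[f"eta_{p}" for p in PARAM_NAMES])
    ebe_df.insert(0, "ID", cohort.ids)
    rse = None
    if st.compute_rse:
        rse = standard_errors(m, data, ebe_df, iiv=())
    return FitResult(model=m, rse_percent=rse, ofv=None, ebe=ebe_df,
                     trace=pd.DataFrame(trace_rows), converged=True,
                     seed=seed, settings=st)


def _trace_converged(trace: pd.DataFrame, st: SAEMSettings) -> bool:
    w = min(st.convergence_window, max(len(trace) // 4, 1))
    tail = trace.iloc[-w:]
    prev = trace.iloc[-2 * w : -w] if len(trace) >= 2 * w else tail
    scale = trace.abs().mean() + 1e-12
    drift = (tail.mean() - prev.mean()).abs() / scale
    return bool((drift < st.convergence_rtol).all())


def _posterior_modes(m, cohort, ebe_df, iiv_idx) -> pd.DataFrame:
    """Refine each subject's eta to the posterior mode (the EBE proper)."""
    log_tv = _log_tv_matrix(m, cohort)
    omega2 = np.array([max(m.omega.get(p, 0.0) ** 2, _OMEGA2_FLOOR) for p in PARAM_NAMES])
    out = ebe_df.copy()
    cols = [f"eta_{p}" for p in PARAM_NAMES]
    for i in range(cohort.n):
        sub = _single_subject(cohort, i)

        def nlp(eta_red):
            eta = np.zeros(4)
            eta[iiv_idx] = eta_red
            phi = (log_tv[i] + eta)[None, :]
            ll = _data_loglik(phi, m, sub)[0]
            return -(ll - 0.5 * np.sum(eta[iiv_idx] ** 2 / omega2[iiv_idx]))

        x0 = out.loc[out.index[i], cols].to_numpy(float)[iiv_idx]
        res = optimize.minimize(nlp, x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400})
        eta = np.zeros(4)
        eta[iiv_idx] = res.x
        out.loc[out.index[i], cols] = eta
    return out


def _single_subject(cohort: _Cohort, i: int) -> "_Cohort":
    sub = _Cohort.__new__(_Cohort)
    sub.ids = [cohort.ids[i]]
    sub.n = 1
    sub.times = cohort.times[i : i + 1]
    sub.y = cohort.y[i : i + 1]
    sub.mask = cohort.mask[i : i + 1]
    sub.dose_t = cohort.dose_t[i : i + 1]
    sub.dose_a = cohort.dose_a[i : i + 1]
    sub.cov_frame = cohort.cov_frame.iloc[i : i + 1]
    sub.n_obs = int(sub.mask.sum())
    return sub


# ---------------------------------------------------------------------------
# parameter packing, EBEs, OFV, RSE
# ---------------------------------------------------------------------------


def parameter_vector(m: PopulationModel) -> Dict[str, float]:
    """Flat named view of the estimated parameters of ``m``."""
    out = {f"{p}_pop": m.pop_value(p) for p in PARAM_NAMES}
    for p in PARAM_NAMES:
        for cov_name, beta in sorted(m.covariate_effects.get(p, {}).items()):
            out[f"beta_{p}_{cov_name}"] = beta
    for p in PARAM_NAMES:
        out[f"omega_{p}"] = m.omega.get(p, 0.0)
    if m.error_model in ("additive", "combined"):
        out["error_a"] = m.error_a
    if m.error_model in ("proportional", "combined"):
        out["error_b"] = m.error_b
    return out


def _set_parameter(m: PopulationModel, name: str, value: float) -> PopulationModel:
    if name.endswith("_pop"):
        return m.with_pop_values(**{name[:-4]: value})
    if name.startswith("beta_"):
        _, pname, cov_name = name.split("_", 2)
        eff = {p: dict(v) for p, v in m.covariate_effects.items()}
        eff.setdefault(pname, {})[cov_name] = value
        return replace(m, covariate_effects=eff)
    if name.startswith("omega_"):
        om = dict(m.omega)
        om[name[6:]] = value
        return replace(m, omega=om)
    if name == "error_a":
        return replace(m, error_a=value)
    if name == "error_b":
        return replace(m, error_b=value)
    raise KeyError(name)


def ebes(m: PopulationModel, data: PKDataset, iiv: Sequence[str] = PARAM_NAMES) -> pd.DataFrame:
    """Empirical Bayes estimates (posterior modes of eta) per subject."""
    cohort = _Cohort(data)
    iiv_idx = [k for k, p in enumerate(PARAM_NAMES) if p in iiv and m.omega.get(p, 0) > 0]
    base = pd.DataFrame(
        np.zeros((cohort.n, 4)), columns=[f"eta_{p}" for p in PARAM_NAMES]
    )
    base.insert(0, "ID", cohort.ids)
    if not iiv_idx:
        return base
    return _posterior_modes(m, cohort, base, iiv_idx)


def ofv(
    m: PopulationModel,
    data: PKDataset,
    nmc: int = 1000,
    seed: int = 0,
    ebe_df: Optional[pd.DataFrame] = None,
    return_se: bool = False,
):
    """-2 log marginal likelihood by importance sampling around the EBEs.

    A multivariate-t proposal (4 df) centred at each subject's posterior
    mode with the local curvature as scale keeps the weights heavy-tailed;
    with a fixed seed the value is reproducible.  If every random effect
    is switched off the likelihood is evaluated directly.
    """
    if nmc < 2:
        raise ValueError("nmc must be at least 2")
    cohort = _Cohort(data)
    iiv_idx = [k for k, p in enumerate(PARAM_NAMES) if m.omega.get(p, 0.0) > np.sqrt(_OMEGA2_FLOOR)]
    log_tv = _log_tv_matrix(m, cohort)
    if not iiv_idx:
        total = float(_data_loglik(log_tv, m, cohort).sum())
        return (-2 * total, 0.0) if return_se else -2 * total

    if ebe_df is None:
        ebe_df = ebes(m, data)
    eta_hat = ebe_df[[f"eta_{p}" for p in PARAM_NAMES]].to_numpy(float)
    omega2 = np.array([max(m.omega.get(p, 0.0) ** 2, _OMEGA2_FLOOR) for p in PARAM_NAMES])
    rng = np.random.default_rng(seed)
    d = len(iiv_idx)
    df_t = 4.0
    total = 0.0
    var_total = 0.0
    for i in range(cohort.n):
        sub = _single_subject(cohort, i)
        mode = eta_hat[i, iiv_idx]

        def nlp(eta_red):
            eta = np.zeros(4)
            eta[iiv_idx] = eta_red
            phi = (log_tv[i] + eta)[None, :]
            return -(
                _data_loglik(phi, m, sub)[0]
                - 0.5 * np.sum(eta_red**2 / omega2[iiv_idx])
            )

        H = _numerical_hessian(nlp, mode)
        try:
            cov = np.linalg.inv(H)
            # symmetrize + ensure positive definite
            cov = 0.5 * (cov + cov.T)
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            logger.info("degenerate proposal covariance for subject %s; "
                        "falling back to the prior", cohort.ids[i])
            cov = np.diag(omega2[iiv_idx])
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((nmc, d))
        w_chi = rng.chisquare(df_t, nmc)
        samples = mode + (z @ L.T) * np.sqrt(df_t / w_chi)[:, None]
        # log proposal density (multivariate t)
        diff = samples - mode
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2 * np.sum(np.log(np.diag(L)))
        logq = (
            special.gammaln((df_t + d) / 2) - special.gammaln(df_t / 2)
            - 0.5 * d * np.log(df_t * np.pi) - 0.5 * logdet
            - 0.5 * (df_t + d) * np.log1p(maha / df_t)
        )
        phi = np.repeat(log_tv[i][None, :], nmc, axis=0)
        phi[:, iiv_idx] += samples
        big = _replicate_subject(sub, nmc)
        ll = _data_loglik(phi, m, big)
        lprior = -0.5 * np.sum(samples**2 / omega2[iiv_idx], axis=1) - 0.5 * np.sum(
            np.log(2 * np.pi * omega2[iiv_idx])
        )
        lw = ll + lprior - logq
        lmax = lw.max()
        wts = np.exp(lw - lmax)
        mean_w = wts.mean()
        total += lmax + np.log(mean_w)
        var_total += wts.var() / (nmc * mean_w**2)
    value = -2.0 * total
    se = 2.0 * np.sqrt(var_total)
    return (value, se) if return_se else value


def _replicate_subject(sub: "_Cohort", n: int) -> "_Cohort":
    rep = _Cohort.__new__(_Cohort)
    rep.ids = sub.ids * n
    rep.n = n
    rep.times = np.repeat(sub.times, n, axis=0)
    rep.y = np.repeat(sub.y, n, axis=0)
    rep.mask = np.repeat(sub.mask, n, axis=0)
    rep.dose_t = np.repeat(sub.dose_t, n, axis=0)
    rep.dose_a = np.repeat(sub.dose_a, n, axis=0)
    rep.cov_frame = sub.cov_frame
    rep.n_obs = int(rep.mask.sum())
    return rep


def _numerical_hessian(fn, x, h=1e-3):
    d = len(x)
    H = np.zeros((d, d))
    f0 = fn(x)
    for a in range(d):
        for b in range(a, d):
            ea = np.zeros(d); ea[a] = h
            eb = np.zeros(d); eb[b] = h
            if a == b:
                H[a, a] = (fn(x + ea) - 2 * f0 + fn(x - ea)) / h**2
            else:
                H[a, b] = H[b, a] = (
                    fn(x + ea + eb) - fn(x + ea - eb) - fn(x - ea + eb) + fn(x - ea - eb)
                ) / (4 * h**2)
    return H


def standard_errors(
    m: PopulationModel,
    data: PKDataset,
    ebe_df: Optional[pd.DataFrame] = None,
    iiv: Sequence[str] = PARAM_NAMES,
) -> Dict[str, float]:
    """Relative standard errors (percent) from a linearized Fisher information.

    The model is linearized in the random effects around each subject's
    EBE (first-order conditional approximation), giving a Gaussian
    marginal per subject; per-subject scores of that marginal are
    accumulated into an empirical Fisher information matrix.  The result
    is deterministic for a given fit.
    """
    cohort = _Cohort(data)
    if ebe_df is None:
        ebe_df = ebes(m, data, iiv)
    eta_hat = ebe_df[[f"eta_{p}" for p in PARAM_NAMES]].to_numpy(float)
    names = list(parameter_vector(m))
    psi0 = np.array([parameter_vector(m)[k] for k in names])

    def subject_loglik(mm: PopulationModel, i: int) -> float:
        sub = _single_subject(cohort, i)
        log_tv = _log_tv_matrix(mm, sub)
        phi_hat = log_tv[0] + eta_hat[i]
        msk = sub.mask[0]
        f0 = _predict_phi(phi_hat[None, :], sub)[0][msk]
        # Jacobian wrt eta by central differences
        J = np.zeros((f0.size, 4))
        h = 1e-4
        for c in range(4):
            up = phi_hat.copy(); up[c] += h
            dn = phi_hat.copy(); dn[c] -= h
            J[:, c] = (
                _predict_phi(up[None, :], sub)[0][msk]
                - _predict_phi(dn[None, :], sub)[0][msk]
            ) / (2 * h)
        omega2 = np.array([mm.omega.get(p, 0.0) ** 2 for p in PARAM_NAMES])
        mean = f0 - J @ eta_hat[i]
        cov = J @ np.diag(omega2) @ J.T + np.diag(
            np.maximum(mm.error_sd(f0), _SD_FLOOR) ** 2
        )
        y = sub.y[0][msk]
        diff = y - mean
        sign, logdet = np.linalg.slogdet(cov)
        sol = np.linalg.solve(cov, diff)
        return float(-0.5 * (logdet + diff @ sol + f0.size * np.log(2 * np.pi)))

    scores = np.zeros((cohort.n, len(names)))
    for j, nm in enumerate(names):
        h = max(abs(psi0[j]) * 1e-4, 1e-7)
        m_up = _set_parameter(m, nm, psi0[j] + h)
        m_dn = _set_parameter(m, nm, psi0[j] - h)
        for i in range(cohort.n):
            scores[i, j] = (subject_loglik(m_up, i) - subject_loglik(m_dn, i)) / (2 * h)
    fim = scores.T @ scores
    se = np.sqrt(np.maximum(np.diag(np.linalg.pinv(fim)), 0.0))
    return {
        nm: float(100.0 * se[j] / abs(psi0[j])) if psi0[j] != 0 else float("inf")
        for j, nm in enumerate(names)
    }


def initial_model(
    data: PKDataset,
    template: Optional[PopulationModel] = None,
) -> PopulationModel:
    """Naive starting values from the pooled data.

    A two-point log-linear slope over the pooled early/late concentrations
    fixes the CL/V1 scale; V2 starts at 3·V1 and Q at 0.1·CL, which is
    deliberately rough — SAEM only needs the right order of magnitude.
    """
    obs = data.observations()
    obs = obs[obs["MDV"] == 0]
    dose = float(data.doses()["AMT"].median())
    early = obs[obs["TIME"] <= 60]
    late = obs[obs["TIME"] > 120]
    c_early = max(float(early["DV"].median()), 1e-6)
    c_late = max(float(late["DV"].median()), 1e-6)
    t_early = float(early["TIME"].median()) / 60.0
    t_late = float(late["TIME"].median()) / 60.0
    ke = max(np.log(c_early / c_late) / max(t_late - t_early, 0.25), 1e-3)
    c0 = c_early * np.exp(ke * t_early)
    v1 = dose / c0
    cl = ke * v1
    base = template or PopulationModel(
        cl_pop=1.0, v1_pop=1.0, q_pop=1.0, v2_pop=1.0,
        omega={p: 0.3 for p in PARAM_NAMES},
    )
    return base.with_pop_values(CL=cl, V1=v1, Q=0.1 * cl, V2=3.0 * v1)


def parameter_table(fit: FitResult) -> pd.DataFrame:
    """Estimates with RSE%, one row per estimated parameter."""
    vec = parameter_vector(fit.model)
    rows = []
    for name, value in vec.items():
        rows.append({
            "parameter": name,
            "estimate": value,
            "rse_percent": fit.rse_percent.get(name) if fit.rse_percent else np.nan,
        })
    return pd.DataFrame(rows)
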