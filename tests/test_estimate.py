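"""SAEM estimation, OFV and standard errors."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cefazopk import SAEMSettings, ofv, saem_fit, simulate_cohort, standard_errors
from cefazopk.dataset import PKDataset
from cefazopk.estimate import parameter_vector
from cefazopk.model import reference_model

NO_IIV = {p: 0.0 for p in ("CL", "V1", "Q", "V2")}


@pytest.fixture(scope="module")
def noise_free():
    truth = dataclasses.replace(reference_model(), omega=NO_IIV, error_b=1e-6)
    data = simulate_cohort(truth, seed=11)
    m0 = dataclasses.replace(
        truth.with_pop_values(CL=truth.cl_pop * 1.3, V1=truth.v1_pop * 0.8,
                              Q=truth.q_pop * 1.3, V2=truth.v2_pop * 0.8),
        error_b=0.1)
    fit = saem_fit(data, m0, SAEMSettings(iiv=(), compute_rse=False), seed=5)
    return truth, data, fit


class TestNoRandomEffectsFit:
    """With omega = 0 the fit degenerates to deterministic weighted NLS."""

    def test_matches_independent_nls_oracle(self, noise_free):
        # oracle: scipy.curve_fit-style pooled weighted NLS coded separately
        from scipy import optimize
        truth, data, fit = noise_free
        obs = data.observations()
        covs = data.covariates()
        rows = obs.merge(covs.reset_index(), on="ID", suffixes=("", "_c"))
        t_h = rows["TIME"].to_numpy() / 60.0
        egfr = rows["EGFR"].to_numpy()
        bsa = rows["BSA"].to_numpy()
        ecc = (rows["ARM"] == "ECC").to_numpy(float)
        miecc = (rows["ARM"] == "MIECC").to_numpy(float)
        y = rows["DV"].to_numpy()

        def predict(theta):
            cl0, bcl, v10, bv1, q, v20, becc, bmiecc = theta
            cl = cl0 + bcl * egfr
            v1 = v10 + bv1 * bsa
            v2 = v20 + becc * ecc + bmiecc * miecc
            k10, k12, k21 = cl / v1, q / v1, q / v2
            s = k10 + k12 + k21
            disc = np.sqrt(s * s - 4 * k10 * k21)
            al, be = (s + disc) / 2, (s - disc) / 2
            a = (al - k21) / (v1 * (al - be))
            b = (k21 - be) / (v1 * (al - be))
            return 2000.0 * (a * np.exp(-al * t_h) + b * np.exp(-be * t_h))

        theta0 = np.array([0.06, 0.4, 4.0, 0.6, 0.25, 20.0, -0.5, -0.5])
        sol = optimize.least_squares(
            lambda th: (y - predict(th)) / predict(th), theta0,
            x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14)
        oracle = dict(zip(["CL_pop", "beta_CL_EGFR", "V1_pop", "beta_V1_BSA",
                           "Q_pop", "V2_pop", "beta_V2_ECC", "beta_V2_MIECC"],
                          sol.x))
        pv = parameter_vector(fit.model)
        for k, v in oracle.items():
            assert pv[k] == pytest.approx(v, rel=5e-3), k

    def test_well_identified_effects_recover_truth(self, noise_free):
        truth, _, fit = noise_free
        pv, tv = parameter_vector(fit.model), parameter_vector(truth)
        for k in ("V1_pop", "beta_V1_BSA", "beta_CL_EGFR"):
            assert pv[k] == pytest.approx(tv[k], rel=5e-3), k


class TestSAEM:
    def test_same_seed_identical_trace(self, cohort_ds, perturbed_start):
        st = SAEMSettings(n_exploration=15, n_smoothing=15, compute_rse=False)
        f1 = saem_fit(cohort_ds, perturbed_start, st, seed=3)
        f2 = saem_fit(cohort_ds, perturbed_start, st, seed=3)
        pd.testing.assert_frame_equal(f1.trace, f2.trace)
        pd.testing.assert_frame_equal(f1.ebe, f2.ebe)

    def test_smoothing_phase_variance_shrinks(self, fitted):
        st = fitted.settings
        smooth = fitted.trace.iloc[st.n_exploration:]
        n = len(smooth)
        w = n // 3
        early = smooth.iloc[:w].std()
        late = smooth.iloc[-w:].std()
        # windowed parameter-path dispersion decreases as the step shrinks
        assert (late <= early + 1e-12).mean() > 0.7

    def test_recovers_residual_error_scale(self, fitted):
        assert fitted.model.error_b == pytest.approx(0.16, abs=0.02)

    def test_ebe_count_matches_subjects(self, fitted, cohort_ds):
        assert len(fitted.ebe) == cohort_ds.n_subjects

    def test_omega_stable_under_subject_relabeling(self, cohort_ds,
                                                   perturbed_start, fast_settings):
        # relabeling permutes which MCMC draws serve which subject, so the
        # estimates agree in distribution, not exactly; the check bounds
        # the discrepancy at the Monte Carlo noise scale of the sampler
        fit1 = saem_fit(cohort_ds, perturbed_start, fast_settings, seed=9)
        df = cohort_ds.df.copy()
        ids = list(cohort_ds.subject_ids)
        relabel = {old: new for old, new in zip(ids, ids[::-1])}
        df["ID"] = df["ID"].map(relabel)
        df = df.sort_values(["ID", "TIME"], kind="stable")
        fit2 = saem_fit(PKDataset(df), perturbed_start, fast_settings, seed=9)
        for p in ("CL", "V1", "Q", "V2"):
            assert fit2.model.omega[p] == pytest.approx(
                fit1.model.omega[p], rel=0.25), p


class TestStandardErrors:
    def test_deterministic_and_positive(self, fitted, cohort_ds):
        r1 = standard_errors(fitted.model, cohort_ds, fitted.ebe)
        r2 = standard_errors(fitted.model, cohort_ds, fitted.ebe)
        assert r1 == r2
        assert all(v > 0 for v in r1.values())


class TestOFV:
    def test_no_iiv_matches_analytic_likelihood(self, ref_model):
        m = dataclasses.replace(ref_model, omega=NO_IIV)
        data = simulate_cohort(m, seed=13)
        val = ofv(m, data, nmc=500, seed=0)
        # direct Gaussian -2 log likelihood at the typical predictions
        from cefazopk.estimate import _Cohort, _log_tv_matrix, _predict_phi
        c = _Cohort(data)
        f = _predict_phi(_log_tv_matrix(m, c), c)
        sd = m.error_sd(f)
        msk = c.mask
        ll = (-0.5 * ((c.y - f) / sd) ** 2 - np.log(sd)
              - 0.5 * np.log(2 * np.pi))[msk].sum()
        assert val == pytest.approx(-2 * ll, rel=1e-12)

    def test_seeded_reproducibility(self, ref_model, cohort_ds, fitted):
        v1 = ofv(ref_model, cohort_ds, nmc=300, seed=4, ebe_df=fitted.ebe)
        v2 = ofv(ref_model, cohort_ds, nmc=300, seed=4, ebe_df=fitted.ebe)
        assert v1 == v2

    def test_monte_carlo_error_scales_with_nmc(self, ref_model, cohort_ds, fitted):
        _, se1 = ofv(ref_model, cohort_ds, nmc=400, seed=4,
                     ebe_df=fitted.ebe, return_se=True)
        _, se2 = ofv(ref_model, cohort_ds, nmc=1600, seed=4,
                     ebe_df=fitted.ebe, return_se=True)
        assert se2 < se1
        assert se1 / se2 == pytest.approx(2.0, rel=0.5)

    def test_true_model_beats_covariate_stripped(self, ref_model):
        # averaged over seeds, dropping the clearance-eGFR relation from
        # the generating model must cost likelihood
        stripped = dataclasses.replace(
            ref_model, covariate_effects={"V1": {"BSA": 0.51},
                                          "V2": {"MIECC": -0.79, "ECC": -0.77}})
        stripped = stripped.with_pop_values(CL=0.045 + 0.49 * 1.4)
        diffs = []
        for seed in (31, 32, 33):
            data = simulate_cohort(ref_model, seed=seed)
            diffs.append(ofv(stripped, data, nmc=300, seed=0)
                         - ofv(ref_model, data, nmc=300, seed=0))
        assert np.mean(diffs) > 0
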