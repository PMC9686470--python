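"""Structural model, covariate model and clinical formulas."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cefazopk.clinical import bsa_dubois, egfr_ckd_epi
from cefazopk.model import (CovariateVector, DegenerateModelError, DoseEvent,
                            IndividualParams, InvalidParameterizationError,
                            PopulationModel, apply_covariates, concentration,
                            concentration_mm, hybrid_constants,
                            reference_model, sample_individual, typical_value)
from _oracles import ode_concentration

params_strategy = st.builds(
    IndividualParams,
    cl=st.floats(0.05, 20.0),
    v1=st.floats(2.0, 30.0),
    v2=st.floats(2.0, 60.0),
    q=st.floats(0.05, 20.0),
)


class TestHybridConstants:
    def test_reference_rate_constants(self):
        # roots of x^2 - (k10+k12+k21) x + k10 k21 for the fitted
        # individual CL=0.71, V1=5.79, V2=21.28, Q=0.28
        h = hybrid_constants(IndividualParams(cl=0.71, v1=5.79, v2=21.28, q=0.28))
        assert h.alpha == pytest.approx(0.1749, abs=2e-4)
        assert h.beta == pytest.approx(0.00923, abs=2e-5)

    @given(params_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_initial_condition_identity(self, p):
        h = hybrid_constants(p)
        assert h.a_coef + h.b_coef == pytest.approx(1.0 / p.v1, abs=1e-12)
        assert h.alpha > h.beta > 0

    def test_q_to_zero_limit(self):
        p = IndividualParams(cl=1.0, v1=5.0, v2=20.0, q=1e-9)
        h = hybrid_constants(p)
        assert h.alpha == pytest.approx(p.cl / p.v1 + p.q / p.v1, rel=1e-6)
        assert h.beta == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_q_raises(self):
        with pytest.raises(DegenerateModelError):
            hybrid_constants(IndividualParams(cl=1.0, v1=5.0, v2=20.0, q=0.0))

    def test_matches_rate_matrix_eigenvalues(self):
        p = IndividualParams(cl=0.71, v1=5.79, v2=21.28, q=0.28)
        k10, k12, k21 = p.cl / p.v1, p.q / p.v1, p.q / p.v2
        eig = np.linalg.eigvals([[-(k10 + k12), k21], [k12, -k21]])
        h = hybrid_constants(p)
        assert sorted(-eig) == pytest.approx([h.beta, h.alpha], rel=1e-10)


class TestConcentration:
    def test_bolus_initial_concentration(self):
        p = IndividualParams(cl=0.71, v1=5.79, v2=21.28, q=0.28)
        c0 = concentration(p, [DoseEvent(0.0, 2000.0)], 0.0)
        assert c0 == pytest.approx(2000.0 / 5.79, rel=1e-12)

    def test_one_compartment_limit(self):
        p = IndividualParams(cl=1.2, v1=6.0, v2=20.0, q=0.0)
        t = np.array([0.0, 30.0, 120.0, 407.0])
        expected = (2000.0 / 6.0) * np.exp(-(1.2 / 6.0) * t / 60.0)
        assert concentration(p, [DoseEvent(0.0, 2000.0)], t) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        p = IndividualParams(cl=1.0, v1=5.0, v2=20.0, q=0.3)
        with pytest.raises(ValueError):
            concentration(p, [DoseEvent(0.0, 2000.0)], -1.0)

    @given(params_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_closed_form_matches_ode(self, p):
        dose = DoseEvent(0.0, 2000.0)
        times = np.linspace(1.0, 407.0, 25)
        closed = concentration(p, [dose], times)
        numeric = ode_concentration(p, dose, times)
        assert closed == pytest.approx(numeric, rel=1e-6)

    def test_superposition_of_multiple_doses(self):
        p = IndividualParams(cl=2.0, v1=6.0, v2=15.0, q=3.0)
        d1, d2 = DoseEvent(0.0, 2000.0), DoseEvent(240.0, 1000.0)
        t = np.array([300.0, 400.0])
        both = concentration(p, [d1, d2], t)
        sum_of = concentration(p, [d1], t) + 1000.0 / 2000.0 * concentration(
            p, [DoseEvent(240.0, 2000.0)], t)
        assert both == pytest.approx(sum_of, rel=1e-12)

    def test_monotone_decline_after_bolus(self):
        p = IndividualParams(cl=1.0, v1=5.8, v2=21.0, q=0.3)
        t = np.arange(0.0, 408.0)
        c = concentration(p, [DoseEvent(0.0, 2000.0)], t)
        assert np.all(np.diff(c) < 0)


class TestMichaelisMenten:
    def test_first_order_limit(self):
        p = IndividualParams(cl=0.71, v1=5.79, v2=21.28, q=0.28)
        times = np.array([0.0, 30.0, 120.0, 407.0])
        lin = concentration(p, [DoseEvent(0.0, 2000.0)], times)
        mm = concentration_mm(p, (p.cl * 1e6, 1e6), [DoseEvent(0.0, 2000.0)], times)
        assert mm == pytest.approx(lin, rel=1e-3)

    def test_mass_conserved_without_elimination(self):
        p = IndividualParams(cl=1.0, v1=5.0, v2=20.0, q=2.0)
        times = np.array([10.0, 60.0, 200.0, 400.0])
        c1, a1, a2, elim = concentration_mm(
            p, (0.0, 5.0), [DoseEvent(0.0, 2000.0)], times, full_output=True)
        assert a1 + a2 + elim == pytest.approx(2000.0, rel=1e-8)
        assert elim == pytest.approx(0.0, abs=1e-6)

    def test_against_second_integrator(self):
        # independent oracle: Radau at tight tolerance on the same system
        from scipy.integrate import solve_ivp

        p = IndividualParams(cl=1.0, v1=5.0, v2=20.0, q=1.5)
        vmax, km = 300.0, 20.0
        k12, k21 = p.q / p.v1, p.q / p.v2

        def rhs(_t, y):
            c1 = y[0] / p.v1
            el = vmax * c1 / (km + c1)
            return [-el - k12 * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1]]

        times = np.array([30.0, 120.0, 400.0])
        sol = solve_ivp(rhs, (0, times.max() / 60), [2000.0, 0.0], method="Radau",
                        t_eval=times / 60, rtol=1e-11, atol=1e-12)
        ours = concentration_mm(p, (vmax, km), [DoseEvent(0.0, 2000.0)], times)
        assert ours == pytest.approx(sol.y[0] / p.v1, rel=1e-6)

    def test_mass_balance_linear_model_on_ode_path(self):
        # linear elimination expressed through the MM solver (Km >> C)
        p = IndividualParams(cl=2.0, v1=5.0, v2=20.0, q=1.0)
        km = 1e7
        times = np.linspace(5.0, 400.0, 9)
        c1, a1, a2, elim = concentration_mm(
            p, (p.cl * km, km), [DoseEvent(0.0, 2000.0)], times, full_output=True)
        assert a1 + a2 + elim == pytest.approx(2000.0, rel=1e-6)


class TestCovariateModel:
    def test_central_volume_worked_value(self, ref_model):
        cov = CovariateVector(egfr=1.4, bsa=1.73)
        assert typical_value(ref_model, "V1", cov) == pytest.approx(5.79, abs=5e-3)

    def test_ecc_peripheral_volume_reduction(self, ref_model):
        cov_none = CovariateVector(egfr=1.4, bsa=1.73, support="NONE")
        cov_ecc = CovariateVector(egfr=1.4, bsa=1.73, support="ECC")
        v2_none = typical_value(ref_model, "V2", cov_none)
        v2_ecc = typical_value(ref_model, "V2", cov_ecc)
        assert v2_ecc == pytest.approx(21.30, abs=5e-3)
        assert round(100 * (1 - v2_ecc / v2_none), 1) == 3.5

    def test_log_linear_mode(self):
        m = reference_model(covariate_mode="log_linear")
        cov = CovariateVector(egfr=1.4, bsa=1.73)
        assert typical_value(m, "V1", cov) == pytest.approx(
            4.91 * math.exp(0.51 * 1.73), rel=1e-12)

    @pytest.mark.parametrize("mode", ["natural_additive", "log_linear"])
    def test_zero_betas_and_etas_return_population_values(self, mode):
        m = dataclasses.replace(reference_model(covariate_mode=mode),
                                covariate_effects={})
        cov = CovariateVector(egfr=2.0, bsa=2.2, support="ECC")
        p = apply_covariates(m, cov, np.zeros(4))
        assert (p.cl, p.v1, p.q, p.v2) == (m.cl_pop, m.v1_pop, m.q_pop, m.v2_pop)

    def test_natural_additive_nonpositive_rejected(self):
        m = dataclasses.replace(reference_model(),
                                covariate_effects={"V1": {"BSA": -3.0}})
        with pytest.raises(InvalidParameterizationError):
            typical_value(m, "V1", CovariateVector(egfr=1.0, bsa=2.0))

    def test_egfr_unit_scale_enters_clearance(self):
        m60 = reference_model(egfr_unit_scale=60.0)
        m1 = reference_model()
        cov = CovariateVector(egfr=1.5, bsa=1.9)
        assert typical_value(m60, "CL", cov) == pytest.approx(
            0.045 + 0.49 * 1.5 * 60.0)
        assert typical_value(m1, "CL", cov) == pytest.approx(0.045 + 0.49 * 1.5)


class TestSampleIndividual:
    def test_zero_omega_gives_typical_individual(self, ref_model):
        m = dataclasses.replace(ref_model,
                                omega={p: 0.0 for p in ("CL", "V1", "Q", "V2")})
        cov = CovariateVector(egfr=1.4, bsa=1.9)
        p = sample_individual(m, cov, np.random.default_rng(0))
        assert p.cl == pytest.approx(typical_value(m, "CL", cov))
        assert p.v2 == pytest.approx(typical_value(m, "V2", cov))

    def test_log_normal_spread_matches_omega(self, ref_model):
        rng = np.random.default_rng(42)
        cov = CovariateVector(egfr=1.4, bsa=1.9)
        draws = np.log([sample_individual(ref_model, cov, rng).cl
                        for _ in range(20000)])
        assert draws.std() == pytest.approx(0.35, abs=0.01)

    def test_seeded_determinism(self, ref_model):
        cov = CovariateVector(egfr=1.4, bsa=1.9)
        p1 = sample_individual(ref_model, cov, np.random.default_rng(123))
        p2 = sample_individual(ref_model, cov, np.random.default_rng(123))
        assert p1 == p2


class TestClinicalFormulas:
    @pytest.mark.parametrize("wt,ht,expected", [(86.0, 171.0, 1.98),
                                                (71.0, 168.0, 1.80)])
    def test_dubois_worked_values(self, wt, ht, expected):
        assert bsa_dubois(wt, ht) == pytest.approx(expected, abs=0.01)

    @given(st.floats(40.0, 140.0), st.floats(150.0, 200.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dubois_weight_homogeneity(self, wt, ht):
        assert bsa_dubois(2 * wt, ht) == pytest.approx(
            2**0.425 * bsa_dubois(wt, ht), rel=1e-12)

    def test_dubois_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bsa_dubois(0.0, 170.0)

    def test_ckd_epi_worked_value(self):
        assert egfr_ckd_epi(80.0, 60.0, "F") == pytest.approx(1.15, abs=0.01)

    def test_ckd_epi_typical_male_in_study_range(self):
        assert 0.48 <= egfr_ckd_epi(84.0, 72.0, "M") <= 2.52

    def test_ckd_epi_decreasing_in_creatinine(self):
        scr = np.linspace(40.0, 200.0, 30)
        vals = egfr_ckd_epi(scr, 65.0, "M")
        assert np.all(np.diff(vals) < 0)

    def test_ckd_epi_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            egfr_ckd_epi(-1.0, 60.0, "M")
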