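"""Virtual-cohort generator: design counts, covariate ranges, reproducibility."""

import dataclasses

import numpy as np
import pytest

from cefazopk import CohortSpec, generate_covariates, generate_design, simulate_cohort
from cefazopk.cohort import _COVARIATE_TABLE, simulate_observations


@pytest.fixture(scope="module")
def default_cohort():
    spec = CohortSpec()
    covs = generate_covariates(spec, seed=0)
    design = generate_design(spec, covs, seed=1)
    return spec, covs, design


class TestCovariates:
    def test_arm_and_sex_structure(self, default_cohort):
        _, covs, _ = default_cohort
        assert len(covs) == 65
        by_arm = {a: [c for c in covs if c.support == a]
                  for a in ("NONE", "ECC", "MIECC")}
        assert (len(by_arm["MIECC"]), len(by_arm["ECC"]), len(by_arm["NONE"])) == (25, 20, 20)
        assert sum(c.sex == "F" for c in by_arm["MIECC"]) == 6
        assert sum(c.sex == "F" for c in by_arm["ECC"]) == 1
        assert sum(c.sex == "F" for c in by_arm["NONE"]) == 3

    def test_sampled_values_within_published_ranges(self, default_cohort):
        _, covs, _ = default_cohort
        for c in covs:
            table = _COVARIATE_TABLE[c.support]
            for attr, key in [("age", "AGE"), ("weight", "WT"), ("height", "HT"),
                              ("serum_creatinine", "SCR"), ("urea", "UREA"),
                              ("albumin", "ALB"), ("bilirubin", "BILI"),
                              ("total_protein", "TPROT")]:
                _, lo, hi = table[key]
                assert lo <= getattr(c, attr) <= hi

    def test_eligibility_constraints_hold(self, default_cohort):
        _, covs, _ = default_cohort
        for c in covs:
            bmi = c.weight / (c.height / 100) ** 2
            assert 17.0 <= bmi <= 35.0
            assert c.serum_creatinine < 200.0

    def test_egfr_derived_from_creatinine(self, default_cohort):
        from cefazopk import egfr_ckd_epi
        _, covs, _ = default_cohort
        for c in covs[:10]:
            assert c.egfr == pytest.approx(
                egfr_ckd_epi(c.serum_creatinine, c.age, c.sex))

    def test_median_matching_across_seeds(self):
        # medians of the generated cohorts track the published medians
        spec = CohortSpec()
        devs = []
        for seed in range(8):
            covs = generate_covariates(spec, seed=seed)
            for arm in ("NONE", "ECC", "MIECC"):
                sub = [c for c in covs if c.support == arm]
                for attr, key in [("age", "AGE"), ("weight", "WT"),
                                  ("height", "HT"), ("serum_creatinine", "SCR")]:
                    med = np.median([getattr(c, attr) for c in sub])
                    target = _COVARIATE_TABLE[arm][key][0]
                    devs.append(abs(med - target) / target)
        assert np.mean(devs) < 0.10
        assert np.max(devs) < 0.25

    def test_seeded_determinism(self):
        spec = CohortSpec()
        assert generate_covariates(spec, seed=5) == generate_covariates(spec, seed=5)

    def test_invalid_spec_names_field(self):
        bad = {a: dict(t) for a, t in _COVARIATE_TABLE.items()}
        bad["ECC"]["AGE"] = (90.0, 44.0, 82.0)  # median outside range
        with pytest.raises(ValueError, match="AGE"):
            CohortSpec(covariate_table=bad)


class TestDesign:
    def test_dose_and_slot_counts(self, default_cohort):
        _, _, design = default_cohort
        assert design.n_subjects == 65
        doses = design.doses()
        assert len(doses) == 65
        assert (doses["AMT"] == 2000.0).all()
        assert (doses["TIME"] == 0.0).all()
        per_subject = design.observations().groupby("ID").size()
        assert (per_subject == 7).all()
        assert len(design.observations()) == 455

    def test_end_of_surgery_window_no_cpb(self, default_cohort):
        _, _, design = default_cohort
        obs = design.observations()
        nominal = {15.0, 30.0, 45.0, 60.0, 120.0, 180.0}
        eos = obs[~obs["TIME"].isin(nominal) & (obs["ARM"] == "NONE")]["TIME"]
        # U(30,60) incision delay + surgery duration within 81-240 min
        assert ((eos >= 111.0) & (eos <= 300.0)).all()


class TestObservationSimulation:
    def test_noise_free_limit_equals_typical_prediction(self, default_cohort, ref_model):
        from cefazopk.model import DoseEvent, concentration, CovariateVector, apply_covariates
        spec, covs, design = default_cohort
        m = dataclasses.replace(
            ref_model, omega={p: 0.0 for p in ("CL", "V1", "Q", "V2")},
            error_b=1e-12)
        ds = simulate_observations(m, design, seed=3)
        sid = ds.subject_ids[0]
        obs = ds.observations()
        sub = obs[obs["ID"] == sid]
        p = apply_covariates(m, ds.covariate_vector(sid), np.zeros(4))
        f = concentration(p, [DoseEvent(0.0, 2000.0)], sub["TIME"].to_numpy())
        assert sub["DV"].to_numpy() == pytest.approx(f, rel=1e-9)

    def test_proportional_error_magnitude(self, ref_model):
        m = dataclasses.replace(ref_model,
                                omega={p: 0.0 for p in ("CL", "V1", "Q", "V2")})
        spec = CohortSpec(n_per_arm={"NONE": 120, "ECC": 120, "MIECC": 150})
        ds = simulate_cohort(m, spec, seed=9)
        from cefazopk.estimate import _Cohort, _log_tv_matrix, _predict_phi
        c = _Cohort(ds)
        f = _predict_phi(_log_tv_matrix(m, c), c)
        ratio = (c.y[c.mask] - f[c.mask]) / f[c.mask]
        assert ratio.std() == pytest.approx(0.16, abs=0.01)

    def test_full_dataset_reproducible(self, ref_model):
        d1 = simulate_cohort(ref_model, seed=21)
        d2 = simulate_cohort(ref_model, seed=21)
        assert d1.df.equals(d2.df)
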