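"""Residual diagnostics (PWRES/IWRES/NPDE) and the visual predictive check."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cefazopk import residuals, simulate_cohort, simulate_reference, vpc
from cefazopk.dataset import PKDataset
from cefazopk.estimate import _Cohort, _log_tv_matrix, _predict_phi
from cefazopk.model import reference_model

NO_IIV = {p: 0.0 for p in ("CL", "V1", "Q", "V2")}


@pytest.fixture(scope="module")
def ref_sims(ref_model, cohort_ds):
    return simulate_reference(ref_model, cohort_ds, nsim=600, seed=8)


class TestSimulateReference:
    def test_noise_free_replicates_equal_typical_predictions(self, cohort_ds):
        m = dataclasses.replace(reference_model(), omega=NO_IIV, error_b=1e-12)
        sims = simulate_reference(m, cohort_ds, nsim=3, seed=0)
        c = _Cohort(cohort_ds)
        f = _predict_phi(_log_tv_matrix(m, c), c)[c.mask]
        for r in range(3):
            assert sims[r] == pytest.approx(f, rel=1e-9)

    def test_seeded_reproducibility(self, ref_model, cohort_ds):
        s1 = simulate_reference(ref_model, cohort_ds, nsim=5, seed=4)
        s2 = simulate_reference(ref_model, cohort_ds, nsim=5, seed=4)
        assert np.array_equal(s1, s2)

    def test_shape_matches_observations(self, ref_sims, cohort_ds):
        assert ref_sims.shape == (600, len(cohort_ds.observations()))


class TestResiduals:
    def test_exact_individual_predictions_zero_iwres(self, cohort_ds):
        # DV set exactly to the typical prediction of an omega-free model
        m = dataclasses.replace(reference_model(), omega=NO_IIV)
        c = _Cohort(cohort_ds)
        f = _predict_phi(_log_tv_matrix(m, c), c)[c.mask]
        df = cohort_ds.df.copy()
        df.loc[df["EVID"] == 0, "DV"] = f
        ds = PKDataset(df)
        res = residuals(m, ds, simulate_reference(m, ds, nsim=50, seed=1))
        assert res.table["IWRES"].abs().max() < 1e-9

    def test_null_npde_close_to_standard_normal(self, ref_model, cohort_ds, ref_sims):
        res = residuals(ref_model, cohort_ds, ref_sims)
        npde = res.table["NPDE"]
        assert -0.15 < npde.mean() < 0.15
        assert 0.8 < npde.var() < 1.2
        assert np.isfinite(res.table[["PWRES", "IWRES", "NPDE"]]).all().all()

    def test_doubled_clearance_shifts_late_npde_negative(self, cohort_ds):
        m = reference_model().with_pop_values(CL=2 * 0.045)
        m = dataclasses.replace(
            m, covariate_effects={**m.covariate_effects,
                                  "CL": {"EGFR": 2 * 0.49}})
        res = residuals(m, cohort_ds, simulate_reference(m, cohort_ds, nsim=400, seed=2))
        late = res.table[res.table["TIME"] >= 120.0]["NPDE"]
        # overstated clearance makes the simulated reference decline too
        # fast, so late observations sit far above it
        assert late.mean() > 0.5

    def test_invariant_to_subject_ordering(self, ref_model, cohort_ds, ref_sims):
        res1 = residuals(ref_model, cohort_ds, ref_sims)
        ids = list(cohort_ds.subject_ids)
        order = {sid: len(ids) - i for i, sid in enumerate(ids)}
        df = cohort_ds.df.copy()
        df["ID"] = df["ID"].map(order)
        df = df.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
        ds2 = PKDataset(df)
        sims2 = simulate_reference(ref_model, ds2, nsim=600, seed=8)
        # reference simulation consumes per-subject draws in cohort order,
        # so rebuild it; compare per original subject via the relabel map
        res2 = residuals(ref_model, ds2, sims2)
        t1 = res1.table.copy()
        t1["ID"] = t1["ID"].map(order)
        merged = t1.merge(res2.table, on=["ID", "TIME"], suffixes=("_a", "_b"))
        assert len(merged) == len(t1)
        # decorrelation is per subject, so residuals only depend on the
        # subject's own simulations: identical up to the simulation seed
        assert merged["IWRES_a"].to_numpy() == pytest.approx(
            merged["IWRES_b"].to_numpy(), abs=1e-9)


class TestVPC:
    def test_calibrated_model_covers_observed_median(self, ref_model, cohort_ds,
                                                     ref_sims):
        bands = vpc(ref_model, cohort_ds, ref=ref_sims)
        t = bands.table
        inside = ((t["obs_p50"] >= t["sim_p50_lo"]) &
                  (t["obs_p50"] <= t["sim_p50_hi"]))
        assert inside.mean() >= 0.7

    def test_about_eighty_percent_between_outer_bands(self, ref_model, cohort_ds,
                                                      ref_sims):
        obs = cohort_ds.observations()
        lo = np.percentile(ref_sims, 10, axis=0)
        hi = np.percentile(ref_sims, 90, axis=0)
        y = obs["DV"].to_numpy()
        frac = np.mean((y >= lo) & (y <= hi))
        assert 0.7 < frac < 0.9

    def test_single_replicate_degenerates_ci(self, ref_model, cohort_ds):
        bands = vpc(ref_model, cohort_ds, nsim=1, seed=3)
        t = bands.table
        for p in (10, 50, 90):
            assert t[f"sim_p{p}_lo"].to_numpy() == pytest.approx(
                t[f"sim_p{p}_hi"].to_numpy())

    def test_bands_widen_with_doubled_omega(self, ref_model, cohort_ds):
        m2 = dataclasses.replace(
            ref_model, omega={k: 2 * v for k, v in ref_model.omega.items()})
        b1 = vpc(ref_model, cohort_ds, nsim=300, seed=5)
        b2 = vpc(m2, cohort_ds, nsim=300, seed=5)
        w1 = (b1.table["sim_p90_hi"] - b1.table["sim_p10_lo"]).to_numpy()
        w2 = (b2.table["sim_p90_hi"] - b2.table["sim_p10_lo"]).to_numpy()
        assert np.all(w2 >= w1)

    def test_small_bins_merged(self, ref_model, cohort_ds):
        bands = vpc(ref_model, cohort_ds, nsim=50, seed=6,
                    bins=[(0.0, 16.0), (16.0, 17.0), (17.0, 500.0)])
        assert (bands.table["n_obs"] >= 5).all()
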