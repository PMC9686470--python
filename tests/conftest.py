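"""Shared fixtures: reference model, simulated cohorts and fast fits."""

import dataclasses

import numpy as np
import pytest

from cefazopk import (CohortSpec, SAEMSettings, reference_model,
                      simulate_cohort)


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def cohort_ds(ref_model):
    """Default 65-subject cohort simulated from the reference model."""
    return simulate_cohort(ref_model, seed=1)


@pytest.fixture(scope="session")
def fast_settings():
    """Short SAEM schedule for tests that only need a reasonable fit."""
    return SAEMSettings(n_exploration=60, n_smoothing=90, compute_rse=False)


@pytest.fixture(scope="session")
def perturbed_start(ref_model):
    """Starting values displaced from the generating model."""
    m0 = ref_model.with_pop_values(
        CL=ref_model.cl_pop * 1.5, V1=ref_model.v1_pop * 0.7,
        Q=ref_model.q_pop * 1.5, V2=ref_model.v2_pop * 0.7,
    )
    return dataclasses.replace(
        m0,
        covariate_effects={"CL": {"EGFR": 0.25}, "V1": {"BSA": 0.25},
                           "V2": {"MIECC": -0.4, "ECC": -0.4}},
        omega={p: 0.3 for p in ("CL", "V1", "Q", "V2")},
        error_b=0.3,
    )


@pytest.fixture(scope="session")
def fitted(cohort_ds, perturbed_start, fast_settings):
    from cefazopk import saem_fit
    return saem_fit(cohort_ds, perturbed_start, fast_settings, seed=7)


@pytest.fixture(scope="session")
def tiny_spec():
    """Reduced cohort for expensive loops (same design, fewer subjects)."""
    return CohortSpec(
        n_per_arm={"NONE": 6, "ECC": 6, "MIECC": 8},
        sex_counts={"NONE": (5, 1), "ECC": (6, 0), "MIECC": (6, 2)},
    )
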