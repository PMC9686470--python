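"""Estimate the population model by SAEM on a simulated cohort.

Simulates the default 65-subject cohort from the final model, then
re-estimates all fixed effects, covariate coefficients, random-effect
SDs and the proportional error from displaced starting values.  A short
schedule is used here so the example runs in seconds; the package
default is 150 exploratory + 350 smoothing iterations.
"""

import dataclasses

from cefazopk import SAEMSettings, reference_model, saem_fit, simulate_cohort
from cefazopk.estimate import parameter_table

truth = reference_model()
data = simulate_cohort(truth, seed=1)

start = truth.with_pop_values(CL=0.07, V1=3.4, Q=0.4, V2=15.0)
start = dataclasses.replace(
    start,
    covariate_effects={"CL": {"EGFR": 0.25}, "V1": {"BSA": 0.25},
                       "V2": {"MIECC": -0.4, "ECC": -0.4}},
    omega={p: 0.3 for p in ("CL", "V1", "Q", "V2")}, error_b=0.3)

fit = saem_fit(data, start,
               SAEMSettings(n_exploration=60, n_smoothing=90, compute_rse=True),
               seed=7)
table = parameter_table(fit)
print(table.round(3).to_string(index=False))
print(f"\nconverged: {fit.converged}")
print("\nWell-identified quantities (V1 and the eGFR/BSA coefficients, the"
      "\nproportional error ~0.16) are recovered closely; the clearance"
      "\nintercept and the peripheral parameters sit on a flat likelihood"
      "\nridge at n=65 and carry large uncertainty - compare the RSE column.")
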