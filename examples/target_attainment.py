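"""Monte Carlo PK/PD target attainment and redosing times.

Simulates populations with different renal-function strata (eGFR in
mL/s/1.73 m²; >2.17 is augmented renal clearance), computes the
probability of keeping the concentration above the MIC for the whole
407-minute window after a 2 g bolus, and the latest time a second dose
must be given so 90% of an augmented-clearance population stays above
the MIC.
"""

from cefazopk import (EGFR_STRATA, PopulationSpec, pta, redose_time,
                      reference_model)

model = reference_model()
pop = PopulationSpec(n_subjects=65, n_replicates=60)

strata = {k: EGFR_STRATA[k] for k in ("full", "below_arc", "arc")}
table = pta(model, pop, seed=1, strata=strata)
wide = table.table.pivot(index="mic", columns="stratum", values="pta_percent")
print("PTA (%) for fT>MIC = 100% over 407 min:")
print(wide.round(1))
print("\nAttainment falls with MIC and is lowest in the augmented-"
      "clearance (arc) stratum, the qualitative pattern that motivates "
      "redosing only for high-clearance patients.")

arc = PopulationSpec(egfr_range=EGFR_STRATA["arc"], n_subjects=65,
                     n_replicates=60)
print("\nlatest redosing time keeping 90% of the arc stratum above MIC:")
for mic in (4.0, 3.0, 2.0, 1.5):
    r = redose_time(model, arc, mic, seed=1)
    print(f"  MIC {mic:>3} mg/L: {r.redose_time_min:6.0f} min")
print("\nTimes shrink as the MIC rises; under the published parameter"
      "\nvalues (slow elimination) they sit far later than the intervals"
      "\nclinical guidance would suggest - see the methods note on the"
      "\nparameter-scale ambiguity of the source estimates.")
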