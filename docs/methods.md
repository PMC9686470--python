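# Methods

## Structural model and units

The disposition model is a linear two-compartment system with first-order
elimination from the central compartment, solved in closed form as a
biexponential for IV boluses and superposed across doses. A
one-compartment limit (Q = 0) and a Michaelis–Menten elimination variant
(rate Vmax·C1/(Km + C1), solved with LSODA at rtol 1e−8 / atol 1e−10)
exist for structural-model comparison; the linear models never go through
an integrator.

Times are minutes at every interface (dosing records, sampling schedules,
simulation grids, redosing times) while all rate parameters are per hour;
the single conversion lives in `cefazopk.units`. Concentrations are mg/L,
doses mg, volumes L.

Clinical covariates: body surface area by DuBois
(0.007184·W^0.425·H^0.725) and eGFR by the CKD-EPI 2009 creatinine
equation without the race term (the emulated cohort is central-European),
converted to SI units (mL/s/1.73 m²; divide mL/min by 60). The CKD-EPI
coefficient table is exposed for substitution.

## Covariate model and its two readings

Inter-individual variability is exactly log-normal in both covariate
modes, P_i = TV_i·exp(η_i), so ω always means the SD of log P. The
typical value TV is either

* `natural_additive` (default): TV = P_pop + Σ β·cov, with MiECC/ECC/sex
  as 0/1 indicators; a non-positive TV anywhere in the covariate domain is
  a hard error, or
* `log_linear`: TV = P_pop·exp(Σ β·cov).

The default is the additive form because it reproduces the two worked
values the source analysis prints (central volume 5.79 L at BSA 1.73 m²;
an ECC peripheral-volume reduction of 3.5%), while its model-definition
footnote is written on the log scale. Both are first-class and every
downstream stage accepts either. eGFR likewise enters through a
configurable unit multiplier (`egfr_unit_scale`, default 1.0 = mL/s as in
the covariate tables; 60 re-expresses it per mL/min), because the source
text uses both units in different places.

### Parameter scale (known inconsistency)

The published fixed effects imply a population clearance of ≈0.7 L/h at
median renal function (≈1.3 L/h at augmented clearance) — a terminal
half-life of days, an order of magnitude below every literature value for
cefazolin and, more importantly, irreconcilable with the source's own
simulation outputs: under these values ≥90% of an augmented-clearance
population stays above MIC 4 mg/L for ≈13 h, not the 215 min the source
reports, and no uniform eGFR rescaling reproduces both reported redosing
times at once (their ratio between MIC 1.5 and 4 is incompatible with the
profile shape). The package therefore computes and reports what the
printed values imply, keeps both interpretation knobs configurable, and
does not silently "correct" any number. Users fitting real data are
unaffected; users simulating from the published values should treat the
absolute attainment times as internally consistent with those values
only.

## Synthetic cohorts

The generator emulates the study design, not any individual patient:

* arms 20/20/25 (none/ECC/MiECC) with the reported per-arm sex counts;
* age, weight, height, creatinine, bilirubin, albumin, total protein and
  urea drawn per arm from truncated log-normal distributions. The SD is
  anchored so the untruncated (0.5, 99.5) percentiles bracket the
  reported range; the location is corrected by a short fixed-point
  iteration so the median after truncation matches the reported median
  (asymmetric truncation otherwise shifts it by up to ~10%);
* weight and height coupled through a Gaussian copula with rank
  correlation 0.5 — a realistic adult body-size association;
* eligibility (BMI 17–35 kg/m², creatinine < 200 µmol/L) enforced by
  rejection, mirroring the exclusion criteria;
* eGFR never sampled directly: always derived from sampled
  creatinine/age/sex via CKD-EPI, which keeps the covariates internally
  consistent and sidesteps a typo in the reported ECC-arm eGFR range;
* dosing 2000 mg at t = 0; sampling at 15/30/45/60/120/180 min plus one
  end-of-surgery time = U(30, 60) min incision delay + an arm-specific
  surgery duration drawn from a truncated log-normal anchored to the
  reported mean and range (a triangular distribution cannot represent the
  MiECC arm, whose mean lies far below the range midpoint);
* observations y = f·(1 + b·ε); simulated values below zero are truncated
  at zero and flagged below-limit. No BLQ likelihood correction is
  applied anywhere (the source reports none).

What the generator does **not** emulate: intra-operative hemodilution
time-courses, fluid balance, CPB-circuit sequestration, missingness, or
assay-specific error structure. Passing tests therefore demonstrate that
the pipeline recovers what it simulates under the study design — they do
not validate the published model against real patients.

## SAEM estimation

The E-step runs, per iteration and subject, 5 cycles of three
Metropolis–Hastings kernels on the log individual parameters: a joint
independent proposal from the prior, a component-wise independent
proposal from the prior, and a component-wise random walk whose scale
adapts toward a 0.3–0.5 acceptance rate. The component-wise prior kernel
matters: the joint proposal is vetoed by well-identified parameters, and
without a per-component refresh the weakly identified Q and V2 under-mix,
biasing their ω down and the residual error up.

Sufficient statistics average all chain states of an iteration and are
smoothed with step 1 during 150 exploratory iterations, then k^−0.7 over
350 smoothing iterations. Exploration is deliberately short relative to
smoothing: with a flat likelihood ridge (see above) a long unit-step
phase lets the ridge directions random-walk, and the smoothing phase then
freezes them wherever they happen to be. Simulated annealing (geometric
floor, rate 0.95) keeps ω and the error parameters from collapsing during
exploration.

The M-step is exact: per-parameter least squares of the smoothed log
individual parameters on the covariate relation (closed-form in
log-linear mode; a bounded trust-region solver with a restart at the
data scale in natural-additive mode, which is multimodal when the
covariate never approaches zero), ω² from the centered second moments,
and the error parameters from the accumulated residual statistics
(1-D/2-D likelihood minimization for the combined model).

ω is floored at 0.01 during estimation: below that the prior pins the
individual parameters to the typical values and the chain cannot track
the data. A model with no random effects at all (`iiv=()`) is fitted
directly by iterated weighted nonlinear least squares — the exact
degenerate limit of the marginal likelihood.

EBEs are posterior modes (Nelder–Mead per subject). The OFV is −2 log
marginal likelihood by importance sampling with a multivariate-t (4 df)
proposal centred at each EBE with the local curvature as scale; a
degenerate curvature falls back to the prior covariance. OFV differences
between nested models share a seed so only likelihood separates them.
Relative standard errors come from an empirical Fisher information of the
first-order-conditional (linearized-at-EBE) marginal — deterministic
given a fit, with the usual caveat that the linearization degrades for
large ω.

Initial values, when not supplied: a two-point log-linear slope on the
pooled early/late concentrations for the CL/V1 scale, V2 = 3·V1,
Q = 0.1·CL.

## Covariate selection

Stage one screens every candidate covariate against every parameter's
EBEs by Pearson correlation (point-biserial for the sex and support
indicators), keeping p < 0.05. Stage two is forward stepwise: each round
refits every remaining candidate on top of the current model and accepts
the largest OFV drop if it is ≥ 3.84 (χ², 1 df, p < 0.05). Backward
elimination is not implemented — the source names a single threshold and
a forward procedure is the parsimonious reading; the threshold is a
parameter for anyone wanting a stricter backward pass.

## Evaluation

* **Bootstrap**: subjects resampled with replacement, stratified by arm,
  500 replicates by default; percentile median and 2.5/97.5 CI per
  parameter; failed refits dropped and counted, >20% failures warned.
  Identity resampling (every replicate the original data under one seed)
  is the degenerate mode whose medians equal the point estimates.
* **Residuals**: IWRES standardizes by the individual error SD
  (√(a² + (b·f)²) in general); PWRES decorrelates each subject's
  observation vector by the Cholesky factor of the empirical simulation
  covariance (1000 replicates by default, ridge-regularized if singular);
  NPDE maps the rank of the decorrelated observation among decorrelated
  simulations through Φ⁻¹ with a half-offset rank so it stays finite.
* **VPC**: observed 10/50/90th percentiles per time bin against the 90%
  interval of the same percentile across replicates. Bins default to the
  nominal sampling times plus a median split of the end-of-surgery tail —
  the design is nominally timed, so richer binning rules add nothing —
  and bins under 5 observations merge with a neighbor.

## Target attainment and redosing

The PK/PD target is fT>MIC = 100% over a 407-minute window (the span of
the emulated concentration data; configurable). A bolus biexponential
declines strictly after t = 0, so attainment over the window equals
attainment at its right edge; the implementation exploits this and the
tests cross-check against a 1-minute (and 0.01-minute) grid scan.

PTA populations draw eGFR uniformly over the stratum bounds (full range
0.67–2.8 mL/s; augmented 2.17–2.8) and every other covariate from the
cohort generator, cycling the study's arm structure — individual
covariate vectors of the source cohort are unpublished, so this is an
approximation that may shift PTA by a few points. Defaults are 500
replicates of 65 subjects; the success threshold is 90%.

`redose_time` returns the largest whole minute t\* with
P(C(s) ≥ MIC ∀ s ≤ t\*) ≥ 0.90, found by bisection on the monotone
attainment curve, with an explicit not-achievable result when even the
first minute fails and a 24-hour grid maximum.

## Problem sizes

Acceptance recomputations use 10,400 simulated subjects for redosing
times and one default 65-subject cohort (fitted with the default
150 + 350 SAEM schedule) for parameter recovery. The test suite runs
shorter SAEM schedules (25–90 iterations per phase) wherever only the
mechanics are under test, and the full schedule where estimates are
compared to reference intervals; VPC/NPDE checks use 400–600 replicates.

## Known limitations

* The clearance intercept, Q and V2 sit on a flat likelihood ridge at
  n = 65 under this design (elimination barely progresses within the
  sampling window at the published parameter scale). Their point
  estimates are seed-sensitive; an ideal estimator's intercept sampling
  SD (~0.056 L/h) exceeds the width of the published bootstrap interval.
  The eGFR coefficient, V1 and the error parameter are robustly
  recovered.
* Estimates are invariant to subject relabeling in distribution only;
  the chains consume randomness in cohort order, so individual runs
  differ at the Monte Carlo noise scale.
* Single-dose, total-concentration analysis: no protein-binding
  correction, no infusion/absorption models, no inter-occasion
  variability, diagonal Ω only, no prediction-corrected or
  covariate-stratified VPC.
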