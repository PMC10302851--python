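# Methods

## The estimation model

Vancomycin is treated as a one-compartment drug given by zero-order
intermittent infusion with first-order elimination, analyzed at steady
state. Each dosing interval of length τ splits into an infusion phase
(duration t_in) and an elimination phase. The per-interval AUC is the sum
of a linear trapezoid over the infusion phase, `t_in·(Cmax + Cmin)/2`, and
the exact exponential area over the elimination phase, `(Cmax − Cmin)/Ke`;
scaling by `24/τ` gives AUC24. The trapezoid is the only approximation:
for exponential kinetics the infusion-phase curve is concave, so the
chord slightly underestimates its area. Because the infusion phase is a
small share of the interval, the induced AUC24 error is well under 1%
whenever `Ke·t_in ≤ 0.2` (measured at ~0.3% worst-case on the synthetic
cohort).

Two estimation branches mirror what level data allow:

* **Two levels** in the same steady-state interval, both drawn after the
  end of the infusion: Ke is observed directly as `ln(C1/C2)/(t2 − t1)`;
  the earlier level is back-extrapolated over the time elapsed since the
  infusion ended to give the true peak, and the true trough is projected
  to the end of the interval. With noise-free exponential data this
  branch inverts the simulator exactly (Ke recovered to machine
  precision).
* **One trough**: Ke is the Matzke population regression
  `Ke = 0.00083·CrCl + 0.0044` (CrCl from Cockcroft–Gault), the measured
  trough is taken as the true trough, and the peak is the algebraic
  inverse of the trough projection, `Cmax = Cmin·e^{Ke(τ−t_in)}`. This
  branch inherits the regression's population-level bias; the synthetic
  cohort quantifies it (see below).

The one-level equation sequence is stated in some references in an order
that cannot be executed literally (the trough-projection step precedes
the availability of a peak). We implement the only algebraically
consistent reading: measured trough → peak by inverse projection → trough
reprojected (a no-op when the draw is at the true trough time). Similarly,
`ln(C1/C2)/(t1 − t2)` appears in print without parentheses; the
implementation uses `(t2 − t1)` so that Ke is positive for a decaying
pair, and the AUC24 composition applies the `24/τ` factor to the whole
per-interval area (the alternative reading would scale only the
elimination term and double-count the infusion phase).

Peak back-extrapolation is referenced to the end of the infusion, with
draw-time bookkeeping in hours since the start of the dose's interval.
Cockcroft–Gault uses actual body weight by default (configurable to
Devine ideal or adjusted weight); the motivating cohort's very high mean
CrCl is consistent with actual-weight use.

## Cohort rules

Exclusions apply in a fixed first-match order: one-time dose, age < 18,
no level available, hemodialysis. Steady state is operationalized as
`dose_number ≥ 4` (≈3–5 half-lives for q8–q24 regimens; configurable) —
the underlying reviews say only "drawn at steady state". Level selection
prefers the earliest steady-state interval containing both a peak and a
trough; otherwise the earliest steady-state trough; an order with neither
is excluded as having no usable level. A peak/trough pair that is
non-physiologic after assay noise (inverted) falls back to the
trough-only branch rather than aborting the cohort run.

Classification boundaries: the 400–600 mg·h/L window is closed (both
endpoints therapeutic); MIC defaults to 1 mg/L, configurable per run.
Obesity is BMI ≥ 30 kg/m² (inclusive). Renal strata put CrCl exactly 30
into the 30–59 group. The AKI rule requires two *consecutive* daily SCr
values each rising ≥ 0.5 mg/dL or ≥ 50% over baseline; the clinical
"absence of alternative explanation" qualifier is not computable from an
order table and is out of scope. Indications are keyword-matched
(case-insensitive) into uncomplicated (cellulitis, UTI/urinary, skin and
soft tissue) vs complicated (CNS/meningitis, pneumonia, bone/joint,
bloodstream/bacteremia, sepsis); anything else is unknown. Analysis is at
the order level, not the unique-patient level.

## Statistics

The 2×2 chi-square is the uncorrected Pearson statistic
`N(ad − bc)²/((a+b)(c+d)(a+c)(b+d))` on 1 df — the published stratified
statistics match the uncorrected form exactly, and Yates-corrected values
would not. The Fisher exact test is two-sided under the probability-mass
convention (sum of hypergeometric probabilities of all tables with the
observed margins no more probable than the observed table); conventions
differ across software, so this choice is stated explicitly and verified
against a full-enumeration oracle in the test suite. Descriptive output
uses the sample SD (n − 1) and linear-interpolation quartiles; printed
percentages round half-up to one decimal.

The reference renal-function Fisher table `[[0,19],[85,201]]` is
reconstructed from published margin counts (19 of 19 low-CrCl orders
above goal, hence zero attainers; 85 attainers overall); the exact table
the original analysts used was not printed, but this reconstruction
reproduces their p = 0.0026 under the probability-mass convention.

## The synthetic cohort

The generator emulates the motivating cohort's order-level structure:
~24.6% female, ~24.6% obese, age 53.8 ± 18.4 y, weight drawn per obesity
stratum (97.5 ± 22.1 kg obese, 67.2 ± 15 kg non-obese, giving ~74.6 kg
overall), SCr per stratum (0.78 ± 0.30 / 0.99 ± 0.77 mg/dL, truncated to
0.4–4.0). Heights are **synthetic**: the source data report obesity class
but no heights, so BMI is drawn within stratum (34 ± 3.5 obese, 25 ± 3
non-obese, truncated at the 30 kg/m² boundary) and height derived as
√(weight/BMI), which matches the obese fraction by construction.

True pharmacokinetics: `Ke_true` is the Matzke prediction perturbed by
log-normal inter-individual variability (default 20% CV), `Vd` is
0.7 L/kg (the standard adult population value) with its own 20% CV, and
`CL = Ke·Vd`. The exact steady-state AUC24 is `dose·(24/τ)/CL`, recorded
per patient as the recovery oracle; a test confirms the closed-form
concentration profile integrates to the same value to < 1e-6 relative.

Dosing emulates renally adjusted trough-based practice: 16.3 mg/kg
(14.4 mg/kg if obese, matching the source cohort's observed
underdosing of obese patients) rounded to 250 mg, interval q8h for
CrCl ≥ 120, q12h for 60–119, q24h below 60, infusion ~1 h per gram.
Levels are drawn in the interval of dose 4 (a peak 1 h after the infusion
ends with probability `pair_fraction` = 0.7 — the source cohort averaged
1.7 levels per order — and a trough 0.5 h before the next dose), from the
closed-form steady-state profile with multiplicative log-normal assay
noise (default CV 10%, mean-preserving). AKI trajectories are injected at
rate 2.6%: two consecutive days exceeding both creatinine criteria;
non-AKI trajectories are clipped strictly below both criteria, so the
detector's behaviour on them is known by construction.

What the generator does **not** emulate: accumulation before steady
state (levels are sampled from the steady-state profile even at dose 4),
two-compartment distribution phases, time-varying renal function (the
injected AKI does not feed back into clearance), missed or delayed doses,
and any correlation between indication and pharmacokinetics. Passing
recovery tests therefore demonstrates the estimators invert the assumed
model and tolerate assay noise — not that the model captures every
feature of real patients. Consistent with that, the published cohort's
attainment split (27.9/34.8/37.4%) is treated purely as a rendering and
calibration fixture, never as a quantity the pipeline should reproduce
from simulated data. One visible consequence of the simplified SCr model
is that the synthetic cohort's mean CrCl (~90 mL/min) sits below the
source cohort's heavily skewed 125 ± 91 mL/min.

## Measured behaviour (computed by the test suite / acceptance script)

* Noise-free two-level estimation over ~140 patients with
  `Ke·t_in ≤ 0.2`: Ke exact to < 1e-15 relative, AUC24 within 0.3% of the
  analytic truth (trapezoid-only error).
* 1000 patients at 10% assay CV, mixed branches (70% two-level): median
  absolute relative AUC24 error ≈ 6%; the one-level Matzke branch is the
  noisier one (median ≈ 9%) because of the 20% inter-individual Ke
  variability it cannot see.
* The four published chi-square statistics and the Fisher p reproduce to
  their printed precision from the reference counts.

Problem sizes (150 noise-free, 1000 noisy patients) were chosen to give
stable medians and tight oracle checks while keeping the default test run
fast.

## Known limitations

Single-compartment, steady-state-only estimation (no Bayesian posterior,
no superposition for non-steady-state draws); no hemodialysis or
pediatric support (excluded populations); AKI attribution ignores
nephrotoxic co-medication and cumulative exposure; keyword indication
matching is deliberately naive.
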