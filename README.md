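# vancotdm

Vancomycin therapeutic drug monitoring (TDM) moved from trough-based
targets to AUC/MIC-based targets: efficacy against *S. aureus* tracks the
ratio of the 24-hour area under the serum concentration–time curve to the
pathogen's MIC, with a guideline window of 400–600 mg·h/L. Many hospitals
still dose by troughs, and a practical way to audit such practice is to
recompute the expected AUC24 of each vancomycin order from the one or two
serum levels that were actually drawn, using first-order pharmacokinetic
equations.

`vancotdm` implements that audit as a tested, reusable package, for
clinical pharmacists and pharmacometricians who want to run or simulate
AUC/MIC target-attainment reviews:

* **Per-order PK estimation** (`vancotdm.pk`). With a steady-state
  peak/trough pair in one interval:
  `Ke = ln(C1/C2)/(t2 − t1)`, the true peak back-extrapolated to the end
  of the infusion `Cmax = C1·e^{Ke·Δt}`, the true trough
  `Cmin = Cmax·e^{−Ke(τ−t_in)}`, and
  `AUC24 = (t_in(Cmax+Cmin)/2 + (Cmax−Cmin)/Ke)·24/τ`
  (linear trapezoid over the infusion, exact exponential area over the
  elimination phase). With a single trough, Ke comes from the Matzke
  population regression `Ke = 0.00083·CrCl + 0.0044` on Cockcroft–Gault
  creatinine clearance and the peak is extrapolated algebraically.
* **Cohort pipeline** (`vancotdm.cohort`). Exclusions (one-time dose,
  age < 18, no usable level, hemodialysis), earliest-steady-state level
  selection, classification against the 400–600 mg·h/L window (MIC
  assumed 1 mg/L by default), stratification by obesity (BMI ≥ 30),
  renal function (< 30 / 30–59 / ≥ 60 mL/min) and indication, and the
  guideline AKI rule (SCr rise ≥ 0.5 mg/dL or ≥ 50% over baseline on two
  consecutive days).
* **Contingency statistics** (`vancotdm.stats`, `vancotdm.reference`).
  Uncorrected Pearson chi-square and two-sided Fisher exact tests on 2×2
  stratified outcomes, plus the published counts of the motivating
  305-order retrospective cohort as reference data.
* **Synthetic cohorts with known truth** (`vancotdm.simulate`).
  Steady-state one-compartment intermittent-infusion patients with
  recorded true Ke, clearance and AUC24 (= 24-h dose / CL), used as the
  recovery oracle for the estimators.
* **I/O, reports and a CLI** (`vancotdm.io`, `vancotdm.cli`).

## Worked example

```python
from vancotdm import pk

regimen = pk.DosingRegimen(dose=1000, tau=12, t_in=1)   # 1 g over 1 h q12h
levels = [
    pk.SerumLevel(concentration=30.0, draw_time=3.0,  dose_number=1, label="peak"),
    pk.SerumLevel(concentration=10.0, draw_time=11.5, dose_number=1, label="trough"),
]
est = pk.estimate_pk_two_level(levels, regimen)
print(f"Ke {est.ke:.4f} /h  Cmax {est.cmax:.2f}  Cmin {est.cmin:.2f}  "
      f"AUC24 {est.auc24:.1f} mg·h/L")
```

prints

```
Ke 0.1292 /h  Cmax 38.85  Cmin 9.37  AUC24 504.3 mg·h/L
```

i.e. the peak drawn 2 h after the end of the infusion decays with a
half-life of ~5.4 h; back-extrapolated to the infusion end the true peak
is 38.85 mg/L, the projected true trough 9.37 mg/L, and the 24-hour AUC
504.3 mg·h/L — inside the 400–600 therapeutic window at MIC 1, so this
order would be classified `therapeutic`.

The same end-to-end from the shell:

```sh
vancotdm simulate --n 305 --seed 0 --out-dir run/
vancotdm estimate --cohort run/cohort.csv --out run/results.csv
vancotdm report   --cohort run/cohort.csv --out-json run/report.json
vancotdm repro-stats
```

`repro-stats` recomputes the published stratified statistics from the
reference counts: chi-square 48.48 (below-goal by obesity), 27.36
(above-goal), 3.06 (therapeutic), 2.86 (AKI), and Fisher exact p = 0.0026
for attainment by CrCl < 30 vs ≥ 30 mL/min.

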