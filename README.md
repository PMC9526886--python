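# irsflow

Intrinsic radiosensitivity (IRS) from γH2AX flow cytometry: a tested
pipeline from event-level fluorescence measurements to per-patient DNA
double-strand-break (DSB) indices and their power to predict acute skin
toxicity during radiotherapy.

## The problem

Patients receiving identical radiotherapy differ widely in how badly their
healthy tissue reacts. A candidate pre-treatment biomarker is the DSB burden
and repair capacity of the patient's own lymphocytes: blood is drawn before
treatment, peripheral blood mononuclear cells are irradiated ex vivo at
0, 1 and 2 Gy, and the phosphorylated histone γH2AX — which accumulates at
DSBs — is measured by flow cytometry 30 min, 3 h and 24 h later. Each tube
is summarised by the **geometric mean** (GM) of the γH2AX fluorescence after
a lymphocyte scatter gate, and each patient is reduced to three indices:

* **DSB induction** at dose D: `GM(D, 30 min) − GM(control)`
* **% residual DSBs** at time t: `100 · [GM(D, t) − GM(control)] / [GM(D, 30 min) − GM(control)]`
* **dose–response slope**: OLS slope of `GM(D, 30 min) − GM(control)` on D (ΔGM/Gy)

The prediction layer tests whether these indices identify *overreactors*
(RTOG acute skin toxicity grade ≥ 2): Pearson correlations with grade,
Gaussian-centile thresholds (mean + k·SD, k ∈ {1, 2}), confusion-matrix
metrics, and ROC analysis with the Youden-optimal cutoff. A film-dosimetry
module (netOD = log₁₀(PV_unexposed/PV_exposed), dose = a·netOD + b·netODⁿ)
summarises the in-vivo skin dose, whose independence from toxicity grade is
the negative control.

Because per-patient clinical data of this kind are not publicly deposited,
the package includes a first-class **synthetic cohort simulator** whose
latent traits (induction slope, baseline GM, repair half-life, grade
coupling) generate event-level log-normal fluorescence with exactly the
structure the analysis assumes — so every stage is testable against known
ground truth.

## Worked example

```python
from irsflow import CohortConfig, RunConfig, analyze
from irsflow.synthetic_cohort import simulate_cohort, cohort_metadata

cohort = CohortConfig(n_patients=50, events_per_sample=5000, seed=42)
patients, samples = simulate_cohort(cohort)
report = analyze(samples, cohort_metadata(patients), RunConfig(cohort=cohort))

print(f"grade >= 2: {report.pct_grade_ge2:.1f}% of {report.n_patients} patients")
print(f"cohort dose-response: slope {report.cohort_slope:.1f} dGM/Gy, R^2 = {report.cohort_r2:.4f}")
for c in report.correlations:
    print(f"{c.index_name:16s} r = {c.r:+.3f}  (p = {c.p_value:.2g})")
roc = report.rocs["slope"]
lo, hi = report.auc_cis["slope"]
print(f"slope ROC: AUC = {roc.auc:.3f} [{lo:.3f}, {hi:.3f}], Youden cutoff = {roc.optimal_cutoff:.1f} dGM/Gy")
```

prints

```
grade >= 2: 40.0% of 50 patients
cohort dose-response: slope 16.1 dGM/Gy, R^2 = 1.0000
dsb_1gy          r = +0.750  (p = 3.7e-10)
dsb_2gy          r = +0.744  (p = 6.2e-10)
residual3h_pct   r = +0.394  (p = 0.0047)
residual24h_pct  r = +0.289  (p = 0.042)
slope            r = +0.744  (p = 6.2e-10)
surface_dose     r = -0.226  (p = 0.11)
slope ROC: AUC = 0.968 [0.894, 1.000], Youden cutoff = 18.0 dGM/Gy
```

Read it as: the cohort-average 30-min GM rises almost perfectly linearly
with dose (R² ≈ 1); induction and slope correlate strongly with toxicity
grade and the residual-damage indices moderately; the measured skin surface
dose does not (it is independent by construction); and the slope index
separates overreactors from the rest with AUC ≈ 0.97 at a cutoff of
~18 ΔGM/Gy for this simulated cohort.

The same run is available from the shell:

```bash
irs report --out out/              # simulate + analyze + write report
irs simulate --config cfg.yaml --out out/
irs analyze --events out/events --meta out/events/cohort.csv --out out/
```

Outputs: `indices.csv` (one row per patient), `correlations.csv`,
`classifier.json`, `roc_<index>.csv` and a human-readable `report.md`; the
same configuration and seed reproduce them byte for byte.

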