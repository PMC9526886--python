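# Methods

## Measurement model

Each flow-cytometry tube is a sample of per-event fluorescence intensities.
The γH2AX (FITC) channel is summarised by the geometric mean

    GM = exp( mean( ln xᵢ ) ),

the natural location statistic for the approximately log-normal fluorescence
distributions flow cytometers record. Nonpositive intensities (possible
after instrument compensation) are excluded by default with a logged count;
a `shift_epsilon` policy exists for fixtures. Gating is declarative — none,
rectangle, or an axis-aligned ellipse on the two scatter channels — rather
than interactive, trading fidelity to a GUI workflow for reproducibility.
Channel roles resolve from an explicit configuration first and
name patterns (FSC/SSC/FITC/PI, with pulse-statistic suffixes stripped)
second; an ambiguous mapping is an error, never a guess. The DNA (PI)
channel is ingested but unused by the indices.

## Radiosensitivity indices

With GM(D, t) the gated geometric mean at ex-vivo dose D and fixation time
t, and the unirradiated 30-min tube as the control:

* induction: `ΔGM(D) = GM(D, 30 min) − GM(control)`. Negative values are
  kept with a warning — clamping would bias slopes.
* residual: `100 · [GM(D, t) − GM(control)] / ΔGM(D)` at t = 3 h and 24 h,
  reported at the highest dose (2 Gy) by default. When ΔGM(D) is below an
  absolute tolerance (1e-9) the residual is undefined (NaN) and the patient
  is dropped pairwise, never listwise, from downstream analyses.
* slope: ordinary least squares of `GM(D, 30 min) − GM(control)` on D,
  including the D = 0 point. "Normalisation with the control" is
  implemented as subtraction, consistent with the induction index being a
  difference; a ratio normalisation would change the estimand. The fit
  keeps an intercept even though the normalised response is zero at D = 0
  by construction, so control-tube noise is absorbed by the intercept
  instead of leaking into the slope. A flat response returns slope 0 with
  R² = 1 (the line fits exactly); R² is otherwise the squared Pearson
  correlation of the fit.

The control could alternatively be taken per timepoint (the 0 Gy tube at
t); in the generative model the 0 Gy GM is time-invariant, and a single
control matches the way the index formulas are written, so the 30-min 0 Gy
tube is used throughout.

## Prediction layer

Overreactors are patients with RTOG acute skin toxicity grade ≥ 2
(configurable). For each index:

* Gaussian-centile threshold: cutoff = mean + k·SD with k ∈ {1, 2}
  (sample SD, n−1). The two-sided "population within ±k·SD" band collapses
  to its upper bound because only overreaction is the positive class; a
  high index is the sensitive direction for all three indices.
* Confusion-matrix metrics in percent; any ratio with a zero denominator is
  reported as undefined (`None`), never imputed as 0.
* ROC over thresholds at every distinct score value; AUC by the trapezoid
  rule, which with rank-average tie handling equals the Mann–Whitney
  statistic (tests verify both equalities against an exhaustive
  pair-counting oracle). The "optimal" cutoff maximises Youden's
  J = sensitivity + specificity − 1, ties broken toward higher specificity.
  A percentile bootstrap CI for the AUC (2000 resamples, seeded; resamples
  with a single class are redrawn) is an engineering addition beyond the
  core analysis.
* Pearson correlations with grade use the two-sided t-transform p-value;
  zero variance is an error, not r = 0. Normality is assessed by a KS test
  against a normal with the sample mean/SD — the p-value is the standard
  asymptotic one and is conservative because the parameters are estimated
  (no Lilliefors correction) — plus the R² of a least-squares Gaussian fit
  to a density histogram (Sturges bins, floor 8). One-way ANOVA compares
  the per-patient 30-min GM across doses.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is validated.
Per patient: induction slope s ~ Normal(15, 8) ΔGM/Gy (truncated positive),
baseline GM b ~ Normal(20, 4), repair half-life h ~ Normal(5, 2) hours
(floored at 0.1). The tube-level geometric mean is

    GM(D, t) = b + s·D·ρ(t),   ρ(0.5 h) = 1,   ρ(t) = 2^(−(t−0.5)/h),

anchoring "induction" at the 30-min timepoint. Per-event FITC intensity is
log-normal around GM with intensity CV 0.8 (σ² = ln(1+CV²)), a typical
width for antibody-stained populations; the log-normal is parameterised so
its geometric mean equals GM exactly. Scatter channels are a clipped
bivariate-normal lymphocyte cluster (FSC ≥ 210) plus a 5% debris fraction
uniform below FSC 150 with a dim FITC signal, so a rectangle gate at
FSC ≥ 200 removes exactly the planted debris.

RTOG grade is the count of fixed cut-points (2.0, 17.9, 26.2, 45.0) lying
below the patient's latent slope, optionally perturbed by ±1 with
probability 0.1. The cut-points place essentially nobody at grades 0 and 4
and ~36% at grade ≥ 2, matching the observed grade distribution of a
50-patient whole-breast cohort, and the slope mean/SD put the sensitive
tail across the ~30 ΔGM/Gy region where the decision threshold falls.
Repair half-life shares a latent Gaussian factor with the slope
(correlation 0.85): sensitive patients repair more slowly, so residual
damage also tracks grade. The latent value is deliberately higher than the
observable correlation it produces (~0.5) because grade discretization and
the nonlinear repair kernel attenuate it. Setting `grade_coupled=False`
severs the slope→grade link for null experiments. Surface doses are
uniform on 0.92–1.9 Gy, independent of everything else — the built-in
negative control. All draws come from one seeded PCG64 generator; the same
config is bit-identical across runs.

What the generator does **not** emulate: cell-cycle structure and
PI-histogram content, apoptotic subpopulations, biphasic (fast+slow) repair
kinetics — a single exponential cannot simultaneously match typical 3 h and
24 h residual levels, so the default half-life of 5 h favours a realistic
3 h residual (~70%) at the cost of a low 24 h one (~4%) — inter-laboratory
batch effects, and measurement drift. Passing tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness to
every artefact of real cytometry data.

## Film dosimetry

Film pieces are reduced upstream to mean red-channel ROI pixel values, so
the module has no imaging dependency. netOD = log₁₀(PV_unexposed /
PV_exposed); calibration dose = a·netOD + b·netODⁿ with n fitted or pinned
(2.5 is conventional for this film type in the red channel), restricted to
doses ≤ 10 Gy where the red channel responds optimally. Monotonicity of the
fitted curve is verified on a dense grid and violations are errors. No
background or glass-scan correction terms are applied. Per-patient summary
is mean ± SD per field position (medial/lateral/central) and pooled; the SD
of a single measurement is reported as 0.

## Numerical and design choices

* FCS support is a minimal, strict FCS 3.1 list-mode reader/writer (linear
  32-bit floats, $PnN names); log-amplified, integer and multi-dataset
  files are rejected explicitly. CSV (`FSC,SSC,FITC,PI`) is the primary
  event dialect, written at 7 significant digits, which preserves geometric
  means to better than 1e-6 relative.
* Event tables are float64 in memory; a 200-patient cohort at 10k
  events/tube (1800 tubes) fits comfortably in a few hundred MB.
* Undefined metrics, residuals and skipped stages are always surfaced
  (logged and listed in the report), never silently dropped.
* Test and validation problem sizes — 200 patients × 10k events for
  parameter recovery, 400 patients for null behaviour, 10⁶ draws for
  centile coverage, 1000 random instances per oracle check — were chosen as
  the smallest sizes at which Monte-Carlo error is negligible relative to
  the tolerances checked.

## Known limitations

* The grade model is a threshold-on-latent construct; it reproduces
  correlated-but-imperfect index↔grade relations but not any particular
  clinical grading process.
* Residual indices at 24 h are small under single-exponential repair, so
  their classifiers are weaker in simulation than the 3 h ones.
* The KS normality p-value is conservative (estimated parameters); use it
  descriptively.
* Threshold classifiers are evaluated in-sample, as in the underlying
  study design; no cross-validation is attempted, and the bootstrap AUC CI
  quantifies only sampling uncertainty, not model-selection optimism.
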