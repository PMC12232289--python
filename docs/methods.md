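# Methods

This note documents the models, numerical choices and simulation design
behind `ogttkit`, and what the validation experiments do and do not
demonstrate.

## Two-compartment C-peptide kinetics

Plasma C-peptide after a unit secretory impulse follows the biexponential
impulse response `h(t) = (1/V_d)·[f·exp(−k_s t) + (1−f)·exp(−k_l t)]` with
`k = ln2/t_half`. The kernel integral `∫h = (f/k_s + (1−f)/k_l)/V_d` is the
reciprocal of the metabolic clearance rate (MCR, L/min), so constant
secretion S settles at the plateau `C = S/MCR`.

Population parameters live in `src/ogttkit/data/kinetic_params.yaml`,
stratified by clinical status (normal / obese / diabetic — the package
defaults to *obese* for a paediatric-obesity cohort; configurable). The
defaults follow the widely used population standardization for OGTT
C-peptide work: short-phase fraction 0.76–0.78, short half-life ≈ 4.5–5 min,
long half-life ≈ 29–32 min, distribution volume linear in body-surface area
(1.92 L/m² + 0.64 L), and a slow age drift of the long half-life
(+0.14 min/year around an adult anchor). The table is config-resident, not
hard-coded, and its hash is recorded in every run log, so a study that
prefers different population constants swaps the YAML. BSA uses Mosteller
`√(w·h/3600)` by default (Du Bois and Haycock selectable) — appropriate for
a paediatric cohort and numerically gentle.

Secretion is represented as piecewise-constant on a 5-minute subgrid
(36 segments on [0, 180]). This makes the convolution exactly integrable —
every matrix entry is a difference of exponentials, no quadrature — and the
inverse problem finite-dimensional. The model assumes a fasting steady
state at t = 0: pre-load secretion was constant long enough that C(0)
determines the fasting ISR via `S_fast = C(0)·MCR` and vice versa.

## Deconvolution

`deconvolve_isr` minimizes

```
Σ_t (C_model(t) − C_obs(t))²  +  λ · Σ_j (Δ² x_j)²,    x_j ≥ 0
```

over absolute segment rates `x`, where `Δ²` is the second difference. The
curvature chain is anchored at the known fasting rate (an extra penalty row
`s_fast − 2x_0 + x_1`), which makes the solution unique for every λ > 0 and
joins the estimate smoothly to the fasting level; the first 0–10 min segment
is otherwise unconstrained by data between samples. Curvature, not slope,
is penalized because secretory pulsatility is unidentifiable at OGTT
sampling density — the estimable object is a smooth secretion trend.

λ is expressed as a multiple of the data-scaled reference
`tr(ΦᵀΦ)/tr(DᵀD)` and selected by generalized cross-validation over a fixed
ladder of 21 log-spaced multipliers spanning 1e-3–1e3. GCV is evaluated on
the unconstrained ridge path, where the effective number of parameters
`df(λ) = tr(Φ(ΦᵀΦ+λDᵀD)⁻¹Φᵀ)` has a closed form; the non-negativity-
constrained solution is then computed once, at the selected λ, by
deterministic NNLS on the stacked (data + penalty) system. Two details
matter numerically:

- `GCV = n·RSS/(n−df)²` diverges as df → n, so near-interpolating λ are
  rejected automatically and noiseless data still select a sensible weight;
- GCV values below the numerical noise floor of the data are treated as
  ties and broken toward the larger (smoother) λ, so exactly representable
  inputs (e.g. constant C-peptide) invert exactly rather than through an
  ill-conditioned small-λ system.

There is no random initialization anywhere; given data and configuration the
estimate is bit-reproducible.

Degenerate inputs: identically-zero C-peptide, a missing t=0 sample, or
fewer than 5 points raise typed errors; the pipeline quarantines such
subjects with a reason rather than failing the run.

## Derived indices

- **Insulin clearance**: CL₀ = S_fast/I(0); CL₁₈₀ = ∫ISR / ∫I over
  [0, 180]. With ISR per m² and insulin in pmol/L both are L·min⁻¹·m⁻².
  These are ratio estimators of the effective clearance of secreted
  insulin, not compartmental parameters; a BSA error applied consistently
  to forward and inverse cancels from the per-m² values (tested).
- **HIRI** = glucose AUC₀₋₃₀ × insulin AUC₀₋₃₀, reported in raw product
  units (insulin pmol/L). Comparisons are rank-based, so the overall scale
  convention is immaterial; what matters is using one convention
  consistently within a cohort.
- **Matsuda WBISI** uses time-weighted trapezoidal means over 0–120 min
  (the index's classic formulation; the window is configurable since 3-hour
  sampling would also permit 0–180).
- **Beta-cell glucose sensitivity** is the least-squares slope of segment
  ISR against glucose (mmol/L) interpolated to segment midpoints. This is
  a deliberate simplification of full beta-cell dose-response modelling:
  rate sensitivity and potentiation are out of scope, and outputs label the
  quantity as the dose-response slope with its R².
- **Stumvoll MCR** uses the demographic variant
  `18.8 − 0.271·BMI − 0.0052·I₁₂₀ − 0.27·G₉₀` (mL·min⁻¹·kg⁻¹), matching the
  unit in which such cohorts report it.
- **OSA classes**: AHI ≤ 1 no OSA (excluded from two-group analysis);
  (1, 5] mild; (5, 10) moderate; ≥ 10 severe; moderate+severe merged for
  analysis. Boundary semantics are exactly these half-open intervals and a
  property test sweeps a dense grid for gaps/overlaps.

## Statistics

Numeric contrasts are screened per group with the Lilliefors
(estimated-parameter Kolmogorov-Smirnov) normality test at α = 0.05: both
groups normal → Student t-test and mean ± SD summaries; otherwise
Mann-Whitney U and median (IQR). The Mann-Whitney p is exact for tie-free
samples with both n ≤ 20, else a normal approximation with continuity
correction. Categorical variables use Fisher's exact test when the table is
2×2 with any expected cell < 5, else chi-square. Curve comparisons run
Mann-Whitney per timepoint with per-point n; points with < 3 subjects per
group are skipped with a note. Spearman correlations use average ranks for
ties; a constant index yields a flagged row, not a failure.

No multiplicity adjustment is applied to primary p-values — the analysis
mirrors small-cohort clinical reporting practice — but every report counts
its tests and carries a supplementary Benjamini-Hochberg column.

## Synthetic cohort

The generator encodes the hypothesized causal structure: AHI → clearance
(negative), clearance → circulating insulin (negative), insulin → HIRI
(positive), with secretion unaffected by AHI. Defaults are chosen to
resemble the target population (children with obesity, median BMI 34,
fasting glucose ≈ 66 mg/dL, fasting insulin ≈ 90–100 pmol/L, fasting
C-peptide ≈ 600–900 pmol/L, cohort 36 mild / 34 moderate–severe):

- **AHI**: log-uniform within (1, 5] (mild) and (5, 25] (moderate–severe) —
  right-skewed, respecting the classifier boundaries.
- **Glucose**: gamma-shaped excursion `G0 + A·(t/t_p)·e^(1−t/t_p)` with
  subject-level baseline (66 ± 8 mg/dL), amplitude (median 70 mg/dL,
  20% CV) and peak time (40 ± 8 min).
- **Secretion**: `ISR(t) = basal + slope·(G(t)−G0)/18` per mM, basal
  100 pmol·min⁻¹·m⁻², slope 140 pmol·min⁻¹·m⁻²·mM⁻¹, 25% between-subject
  CV; C-peptide is the exact forward convolution.
- **Insulin**: one post-hepatic pool with hepatic first-pass survival
  f = 0.5 and subject clearance
  `CL = cl_ref·exp(ahi_effect·log1p(AHI))·exp(N(0, 0.25))`,
  cl_ref = 1.45 L·min⁻¹·m⁻². The stored truth is the *effective* clearance
  (secretion over concentration at steady state), which is what the
  pipeline's ratio estimators target — f is absorbed into its scale, so
  recovery can be judged by relative error rather than through an
  unidentifiable compartmental parameter. The default `ahi_effect = −0.17`
  produces a ≈ 20% median clearance deficit in the moderate–severe group;
  `ahi_effect_for_deficit` computes the coupling for any target deficit.
- **Assay noise**: multiplicative Gaussian, CV 2% (glucose), 5% (insulin),
  4% (C-peptide) — typical clinical immunoassay precision.

All randomness derives from one seed through named substreams
(anthropometry / ahi / curves / noise) keyed positionally per subject, so a
single component can be held fixed while others vary.

What the generator does **not** emulate: closed-loop glucose–insulin
feedback (curves are template-driven, not a physiologic whole-body model),
incretin effects, within-assay drift, missing-visit patterns, or any direct
AHI effect on secretion or glucose tolerance. Passing recovery tests
therefore show that the estimation chain is correct and well-calibrated
under its own assumptions — not that those assumptions hold in any
particular patient cohort. One visible consequence: the simulated
time-averaged total ISR (≈ 400 pmol·min⁻¹·m⁻²) is self-consistent with a
140 pmol·min⁻¹·m⁻²·mM⁻¹ dose-response over a ~4 mM excursion, and cohorts
reporting much lower total ISR alongside similar glucose sensitivity are
using a different normalization; rank-based conclusions are unaffected.

## Validation experiments (what `scripts/acceptance.py` recomputes)

1. **Round trip**: noiseless C-peptide from a smooth known ISR, inverted;
   relative L2 error on [10, 180] min is ≈ 0.3% (bound 5%).
2. **Closed forms**: constant-secretion plateau vs the analytic steady
   state (evaluated after 30 long half-lives, residual transient ~2⁻³⁰);
   impulse-response boundary values; hand-evaluated index oracles.
3. **Clearance recovery**: noiseless n=70 cohort — fraction of subjects
   with CL₁₈₀ within 10% of truth (observed 100%); with assay noise,
   Spearman(truth, estimate) ≈ 0.99.
4. **Effect direction and power**: at a 20% median deficit, 100 replicates
   of the full pipeline at n = 36/34.
5. **Null calibration**: `ahi_effect = 0`, 1000 replicates; false-positive
   rates of the group contrast and the AHI correlation at p < 0.05 sit at
   the nominal 5%.
6. **Exact statistical oracles**: Mann-Whitney vs full enumeration
   (n ≤ 8 per group), Fisher vs the hypergeometric tail sum, and the OSA
   classifier's partition of a dense AHI grid.

Problem sizes (70 subjects, 100/1000 replicates) are the smallest at which
the binomial noise of the measured rates is comfortably inside the asserted
bands; the full suite runs in minutes on one core.

## Known limitations

- Kinetic constants are population values; no per-subject bolus
  calibration is supported, so systematic kinetic misspecification maps
  into proportional ISR (and clearance) bias. Rank-based cohort contrasts
  are robust to this; absolute levels are not.
- The Matsuda 0–120 vs 0–180 window and the Stumvoll variant are
  conventions exposed in configuration; cross-study comparisons must match
  conventions.
- The beta-cell "glucose sensitivity" here is a dose-response slope, not a
  full beta-cell model; it recovers a generator slope within ~15% under
  assay noise but is not interchangeable with model-based estimates.
- HIRI units depend on the insulin unit convention; only ranks are
  comparable across conventions.
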