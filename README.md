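# ogttkit

Analysis toolkit for 3-hour oral glucose tolerance tests (OGTT) in cohort
studies of glucose homeostasis — built around the question of whether
obstructive sleep apnea (OSA) severity in children and adolescents with
obesity is associated with impaired endogenous **insulin clearance** and
**hepatic insulin resistance**, rather than with altered insulin secretion.

It is intended for clinical researchers who have per-subject OGTT sampling
(glucose, insulin, C-peptide at t = 0, 10, 20, 30, 60, 90, 120, 150, 180 min),
basic anthropometry, and a nocturnal polygraphy apnea–hypopnea index (AHI),
and who want a reproducible, fully tested path from raw curves to the derived
indices and the cohort-level statistics.

## What it computes

**Insulin secretion by C-peptide deconvolution.** C-peptide is co-secreted
with insulin 1:1 and escapes hepatic first-pass extraction, so plasma
C-peptide is the convolution of the insulin secretion rate (ISR) with a
two-compartment impulse response

```
h(t) = (1/V_d) · [ f·e^(−k_s t) + (1−f)·e^(−k_l t) ],   k = ln2 / t_half
```

with population kinetic constants standardized to clinical status, body
surface area and age. `deconvolve_isr` inverts this model by non-negative
least squares on 5-minute piecewise-constant segments with a squared
second-difference (curvature) penalty, the weight chosen by generalized
cross-validation; the fasting steady state is anchored to C-peptide at t=0.

**Derived indices** (`metabolic_indices`):

- CL₀ = ISR_fast / I_fast and CL₁₈₀ = AUC(ISR) / AUC(insulin), the fasting
  and post-load endogenous insulin clearance (L·min⁻¹·m⁻²);
- HIRI = glucose AUC₀₋₃₀ × insulin AUC₀₋₃₀, the hepatic insulin resistance
  index;
- Matsuda whole-body insulin sensitivity index, HOMA-IR, Stumvoll MCR;
- beta-cell glucose sensitivity as the ISR-vs-glucose dose–response slope
  (pmol·min⁻¹·m⁻²·mM⁻¹);
- OSA severity classes from AHI (mild 1 < AHI ≤ 5; moderate 5 < AHI < 10;
  severe AHI ≥ 10; moderate and severe analysed together).

**Cohort statistics** (`cohort_stats`): Lilliefors-screened t-test /
Mann-Whitney group contrasts, Fisher/chi-square for categorical variables,
point-by-point OGTT curve comparisons, and Spearman correlations of every
index with AHI.

**Synthetic cohorts with known truth** (`synthetic_cohort`): a generator
that emulates the study population (glucose excursion templates, dose-
response beta-cell secretion, exact forward C-peptide kinetics, a
post-hepatic insulin pool with subject-specific clearance negatively coupled
to AHI) so that every stage of the pipeline can be validated by parameter
recovery without patient data.

## Worked example

```python
from ogttkit import SimulationConfig
from ogttkit.pipeline import RunConfig, run_pipeline

written = run_pipeline(
    RunConfig(simulate=SimulationConfig(n_mild=36, n_modsev=34),
              outdir="demo_out", seed=42)
)
```

This simulates a 70-subject cohort (36 mild, 34 moderate–severe OSA),
deconvolves every subject's ISR, computes the index panel, and writes
`indices.csv`, `group_table.csv`, `curve_table.csv`, `corr_table.csv` and a
run log. The group table it printed for this seed:

```
     variable                mild     moderate_severe         test        p
matsuda_wbisi     4.14 (3.41-6.1)    3.43 (2.58-4.16) mann_whitney 0.002293
         hiri 2.54e+07 ± 9.41e+06 3.07e+07 ± 1.06e+07       t_test 0.030672
     cl_basal    1.2 (0.953-1.59)   0.963 (0.84-1.14) mann_whitney 0.007778
     cl_total    1.23 (1.03-1.54)  0.947 (0.876-1.16) mann_whitney 0.002120
    total_isr       365 (316-443)       407 (367-488) mann_whitney 0.083050
```

and the correlation table:

```
    index  spearman_r        p  n
 cl_basal   -0.352778 0.002741 70
 cl_total   -0.368069 0.001719 70
     hiri    0.248360 0.038162 70
total_isr    0.222885 0.063651 70
```

Read: under the built-in effect structure (a ~20% median clearance deficit
at moderate–severe AHI), the pipeline reports lower post-load insulin
clearance (median 0.95 vs 1.23 L·min⁻¹·m⁻², Mann-Whitney p ≈ 0.002), higher
hepatic insulin resistance, negative AHI–clearance and positive AHI–HIRI
Spearman correlations — while secretion itself does not differ
significantly. The same entry points accept real cohort CSVs via
`RunConfig(read_path=...)` or the CLI:

```
ogttkit simulate --seed 42 --out cohort.csv
ogttkit analyze --in cohort.csv --outdir out/
ogttkit recover --seed 2 --replicates 20 --deficit 0.2
```

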