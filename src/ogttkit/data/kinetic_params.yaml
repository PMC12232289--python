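# Population two-compartment C-peptide kinetic parameters.
#
# The impulse response of plasma C-peptide to a unit secretory impulse is
#   h(t) = (1/vd) * [f * exp(-k_short t) + (1 - f) * exp(-k_long t)],
# with k = ln(2) / half-life.  Population values are stratified by clinical
# status and standardized to the subject's body size (distribution volume
# linear in body-surface area) and age (long half-life drifts slowly with
# age).  Values follow the widely used population standardization for
# OGTT C-peptide deconvolution; every run log records this file's hash so
# an alternative table can be swapped in transparently.
version: 1
bsa_formula: mosteller        # mosteller | dubois | haycock
statuses:
  normal:
    frac_short: 0.76
    halflife_short_min: 4.95
    halflife_long_min: 29.2
  obese:
    frac_short: 0.78
    halflife_short_min: 4.55
    halflife_long_min: 32.3
  diabetic:
    frac_short: 0.78
    halflife_short_min: 4.52
    halflife_long_min: 35.1
volume:
  slope_l_per_m2: 1.92        # vd = slope * BSA + intercept  (litres)
  intercept_l: 0.64
age_adjustment:
  halflife_long_min_per_year: 0.14
  reference_age_years: 35.0   # table values anchored at the adult reference
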