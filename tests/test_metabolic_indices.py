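"""Index formulas against hand-evaluated oracles, scaling laws, OSA grading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ogttkit import (
    OGTTSeries,
    SubjectRecord,
    auc_trapezoid,
    classify_osa,
    deconvolve_isr,
    forward_cpeptide,
    glucose_sensitivity,
    hiri,
    homa_ir,
    insulin_clearance,
    matsuda_index,
    standardize_params,
    stumvoll_mcr,
)
from ogttkit.errors import DomainError, InputError, WindowError
from ogttkit.isr_deconvolution import ISRProfile
from ogttkit.synthetic_cohort import SimulationConfig, simulate_subject, subject_streams

from conftest import OBS_GRID, make_series

SEG = np.arange(0.0, 180.0, 5.0)


# --- AUC ------------------------------------------------------------------


def test_auc_constant_function():
    t = np.array([0, 10, 20, 30.0])
    assert auc_trapezoid(t, np.full(4, 7.0), 0, 30) == pytest.approx(210.0)


def test_auc_exact_on_linear():
    t = np.array([0, 10, 20, 30, 60.0])
    v = 2.0 * t + 5.0
    assert auc_trapezoid(t, v, 0, 60) == pytest.approx(60**2 + 5 * 60)


def test_auc_hand_summation_oracle():
    t = np.array([0, 10, 20, 30.0])
    g = np.array([90, 120, 140, 150.0])
    brute = (90 + 120) / 2 * 10 + (120 + 140) / 2 * 10 + (140 + 150) / 2 * 10
    assert auc_trapezoid(t, g, 0, 30) == pytest.approx(brute, rel=1e-12)


def test_auc_window_errors():
    t = np.array([0, 10.0])
    with pytest.raises(WindowError):
        auc_trapezoid(t, t, 10, 10)
    with pytest.raises(WindowError):
        auc_trapezoid(t, t, 0, 20)


# --- HOMA-IR --------------------------------------------------------------


def test_homa_ir_hand_value():
    """g0=90 mg/dL, i0=108 pmol/L (18 uU/mL) -> 90*18/405 = 4.0."""
    assert homa_ir(90.0, 108.0) == pytest.approx(4.0, rel=1e-12)


def test_homa_ir_linear_in_insulin():
    assert homa_ir(90.0, 216.0) == pytest.approx(2 * homa_ir(90.0, 108.0))
    assert homa_ir(90.0, 1e-4) < 1e-5


def test_homa_ir_domain():
    with pytest.raises(DomainError):
        homa_ir(0.0, 108.0)


# --- Matsuda --------------------------------------------------------------


def test_matsuda_flat_curves_closed_form(flat_series):
    """Flat G=90, I=10 uU/mL -> 10000/(90*10) = 11.11..."""
    assert matsuda_index(flat_series) == pytest.approx(10000.0 / 900.0, rel=1e-12)


def test_matsuda_quarter_scaling(flat_series):
    """Both insulin factors under the square root scale, so multiplying the
    whole insulin curve by 4 divides the index by 4."""
    scaled = make_series(
        flat_series.glucose, 4.0 * flat_series.insulin, flat_series.cpeptide
    )
    assert matsuda_index(scaled) == pytest.approx(matsuda_index(flat_series) / 4.0, rel=1e-12)


def test_matsuda_positive_and_opposite_to_homa(flat_series):
    """Pointwise insulin scaling moves HOMA-IR up and Matsuda down."""
    for f in (0.5, 1.0, 2.0, 5.0):
        s = make_series(flat_series.glucose, f * flat_series.insulin, flat_series.cpeptide)
        assert matsuda_index(s) > 0
    low = make_series(flat_series.glucose, flat_series.insulin, flat_series.cpeptide)
    high = make_series(flat_series.glucose, 2 * flat_series.insulin, flat_series.cpeptide)
    assert homa_ir(high.glucose[0], high.insulin[0]) > homa_ir(low.glucose[0], low.insulin[0])
    assert matsuda_index(high) < matsuda_index(low)


# --- HIRI -----------------------------------------------------------------


def test_hiri_constant_curves():
    s = make_series(np.full(9, 100.0), np.full(9, 100.0), np.full(9, 700.0))
    assert hiri(s) == pytest.approx(3000.0 * 3000.0, rel=1e-12)


def test_hiri_composition_of_hand_oracles():
    g = np.array([90, 120, 140, 150, 150, 150, 150, 150, 150.0])
    i = np.array([60, 90, 120, 150, 150, 150, 150, 150, 150.0])
    g_auc = (90 + 120) / 2 * 10 + (120 + 140) / 2 * 10 + (140 + 150) / 2 * 10
    i_auc = (60 + 90) / 2 * 10 + (90 + 120) / 2 * 10 + (120 + 150) / 2 * 10
    s = make_series(g, i, np.full(9, 700.0))
    assert hiri(s) == pytest.approx(g_auc * i_auc, rel=1e-12)


def test_hiri_bilinear_and_monotone():
    g = np.linspace(90, 150, 9)
    i = np.linspace(60, 200, 9)
    s = make_series(g, i, np.full(9, 700.0))
    s2 = make_series(g, 2 * i, np.full(9, 700.0))
    assert hiri(s2) == pytest.approx(2 * hiri(s), rel=1e-12)
    s3 = make_series(g + 10, i, np.full(9, 700.0))
    assert hiri(s3) > hiri(s)


def test_hiri_missing_early_points():
    s = make_series(
        np.full(5, 100.0), np.full(5, 100.0), np.full(5, 700.0),
        times=[0, 60, 90, 120, 180],
    )
    with pytest.raises(InputError):
        hiri(s)


# --- Clearance ------------------------------------------------------------


def _profile(values, bsa, seg=SEG):
    values = np.asarray(values, float)
    return ISRProfile(
        times=seg, isr=values, bsa=bsa, fasting_isr=float(values[0]),
        isr_auc=float(values.sum() * 5.0), regularization_weight=1.0, fit_rmse=0.0,
    )


def test_clearance_unit_ratios(obese_params, flat_series):
    prof = _profile(np.full(SEG.size, 100.0), obese_params.bsa)
    series = make_series(np.full(9, 90.0), np.full(9, 100.0), np.full(9, 700.0))
    cl0, cl180 = insulin_clearance(prof, series)
    assert cl0 == pytest.approx(1.0, rel=1e-12)
    assert cl180 == pytest.approx(1.0, rel=1e-12)


def test_clearance_constant_80_over_80(obese_params):
    prof = _profile(np.full(SEG.size, 80.0), obese_params.bsa)
    series = make_series(np.full(9, 120.0), np.full(9, 80.0), np.full(9, 700.0))
    _, cl180 = insulin_clearance(prof, series)
    assert cl180 == pytest.approx(1.0, rel=1e-12)


def test_clearance_inverse_insulin_scaling(obese_params):
    prof = _profile(np.linspace(80, 200, SEG.size), obese_params.bsa)
    ins = np.linspace(60, 300, 9)
    s1 = make_series(np.full(9, 100.0), ins, np.full(9, 700.0))
    s2 = make_series(np.full(9, 100.0), ins / 2.0, np.full(9, 700.0))
    cl1 = insulin_clearance(prof, s1)
    cl2 = insulin_clearance(prof, s2)
    assert cl2[0] == pytest.approx(2 * cl1[0], rel=1e-12)
    assert cl2[1] == pytest.approx(2 * cl1[1], rel=1e-12)


def test_clearance_invariant_to_joint_bsa_error(ref_subject):
    """A BSA error applied consistently in forward and inverse cancels from
    the per-m² clearance estimates."""
    import dataclasses

    params = standardize_params(ref_subject, "obese")
    wrong = dataclasses.replace(params, bsa=params.bsa * 1.2)
    mid = SEG + 2.5
    isr_m2 = 100 + 300 * np.exp(-0.5 * ((mid - 60) / 35) ** 2)
    ins = np.full(9, 120.0)  # insulin concentration unaffected by BSA scale
    for p in (params, wrong):
        c0 = isr_m2[0] * p.bsa / p.mcr
        cpep = forward_cpeptide((SEG, isr_m2), p, c0, OBS_GRID)
        prof = deconvolve_isr((OBS_GRID, cpep), p)
        series = make_series(np.full(9, 100.0), ins, cpep)
        if p is params:
            base = insulin_clearance(prof, series)
        else:
            perturbed = insulin_clearance(prof, series)
    assert perturbed[0] == pytest.approx(base[0], rel=1e-6)
    assert perturbed[1] == pytest.approx(base[1], rel=5e-3)


def test_clearance_zero_insulin_domain(obese_params):
    prof = _profile(np.full(SEG.size, 80.0), obese_params.bsa)
    series = make_series(np.full(9, 100.0), np.zeros(9), np.full(9, 700.0))
    with pytest.raises(DomainError):
        insulin_clearance(prof, series)


# --- Glucose sensitivity --------------------------------------------------


def test_glucose_sensitivity_exact_linear_recovery(obese_params):
    g = np.interp(SEG + 2.5, OBS_GRID, np.linspace(80, 180, 9))
    b = 140.0
    isr = 50.0 + b * g / 18.0
    prof = _profile(isr, obese_params.bsa)
    series = make_series(np.linspace(80, 180, 9), np.full(9, 100.0), np.full(9, 700.0))
    slope, r2 = glucose_sensitivity(prof, series)
    assert slope == pytest.approx(b, rel=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-9)


def test_glucose_sensitivity_flat_response(obese_params):
    prof = _profile(np.full(SEG.size, 90.0), obese_params.bsa)
    series = make_series(np.linspace(80, 180, 9), np.full(9, 100.0), np.full(9, 700.0))
    slope, _ = glucose_sensitivity(prof, series)
    assert slope == pytest.approx(0.0, abs=1e-9)


def test_glucose_sensitivity_zero_variance(obese_params):
    prof = _profile(np.full(SEG.size, 90.0), obese_params.bsa)
    series = make_series(np.full(9, 100.0), np.full(9, 100.0), np.full(9, 700.0))
    with pytest.raises(DomainError):
        glucose_sensitivity(prof, series)


def test_glucose_sensitivity_parameter_recovery():
    """Simulated subjects with dose-response slope 140 and assay noise:
    the pipeline's median estimate over 50 replicates is within 15%."""
    cfg = SimulationConfig(
        glucose_slope=140.0, beta_cell_cv=0.0, seed=0,
    )
    estimates = []
    for i in range(50):
        streams = subject_streams(777, i)
        record, series, truth = simulate_subject(cfg, streams, group="mild", subject_id=f"R{i}")
        params = standardize_params(record, "obese")
        prof = deconvolve_isr(series, params)
        slope, _ = glucose_sensitivity(prof, series)
        estimates.append(slope)
    med = float(np.median(estimates))
    assert abs(med - 140.0) / 140.0 <= 0.15


# --- Stumvoll -------------------------------------------------------------


def test_stumvoll_hand_value():
    """BMI 35, I120=600 pmol/L, G90=6 mmol/L -> 18.8-9.485-3.12-1.62."""
    subject = SubjectRecord("s", 12.0, "F", 87.5, 158.1, 3.0, bmi=35.0)
    ins = np.full(9, 600.0)
    glu = np.full(9, 6.0 * 18.0)
    s = make_series(glu, ins, np.full(9, 700.0))
    assert stumvoll_mcr(s, subject) == pytest.approx(4.575, rel=1e-9)


def test_stumvoll_decreases_with_bmi():
    ins = np.full(9, 600.0)
    glu = np.full(9, 108.0)
    s = make_series(glu, ins, np.full(9, 700.0))
    lo = SubjectRecord("a", 12.0, "F", 75.0, 158.1, 3.0, bmi=30.0)
    hi = SubjectRecord("b", 12.0, "F", 87.5, 158.1, 3.0, bmi=35.0)
    assert stumvoll_mcr(s, hi) < stumvoll_mcr(s, lo)


def test_stumvoll_missing_timepoint():
    subject = SubjectRecord("s", 12.0, "F", 87.5, 158.1, 3.0, bmi=35.0)
    s = make_series(
        np.full(5, 108.0), np.full(5, 600.0), np.full(5, 700.0),
        times=[0, 10, 20, 30, 60],
    )
    with pytest.raises(InputError):
        stumvoll_mcr(s, subject)


# --- OSA classification ---------------------------------------------------


@pytest.mark.parametrize(
    "ahi, label, group",
    [
        (0.8, "none", "excluded"),
        (1.0, "none", "excluded"),
        (3.0, "mild", "mild"),
        (5.0, "mild", "mild"),
        (5.01, "moderate", "moderate_severe"),
        (9.99, "moderate", "moderate_severe"),
        (10.0, "severe", "moderate_severe"),
        (42.0, "severe", "moderate_severe"),
    ],
)
def test_classify_osa_thresholds(ahi, label, group):
    osa = classify_osa(ahi)
    assert osa.label == label
    assert osa.analysis_group == group


def test_classify_osa_negative_rejected():
    with pytest.raises(DomainError):
        classify_osa(-0.1)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
def test_classify_osa_partitions_half_line(ahi):
    """Every admissible AHI maps to exactly one severity class."""
    osa = classify_osa(ahi)
    assert osa.label in ("none", "mild", "moderate", "severe")
    expected = (
        "none" if ahi <= 1 else "mild" if ahi <= 5 else "moderate" if ahi < 10 else "severe"
    )
    assert osa.label == expected
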