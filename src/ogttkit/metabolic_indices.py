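"""Scalar OGTT-derived indices of insulin secretion, sensitivity and clearance.

All operations take canonical units (glucose mg/dL, insulin pmol/L,
C-peptide pmol/L, minutes).  Published formulas that are defined for insulin
in uU/mL or glucose in mmol/L convert internally (1 uU/mL = 6.0 pmol/L,
1 mmol/L = 18.0 mg/dL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .cohort_io import OGTTSeries, OSAClass, SubjectRecord
from .errors import DomainError, InputError, WindowError
from .isr_deconvolution import ISRProfile, isr_summaries

INSULIN_PMOL_PER_UU = 6.0
GLUCOSE_MGDL_PER_MM = 18.0


@dataclass
class IndexPanel:
    """All derived scalar indices for one subject."""

    homa_ir: float
    matsuda_wbisi: float
    stumvoll_mcr: float  # mL·min⁻¹·kg⁻¹
    hiri: float  # (mg/dL·min)·(pmol/L·min)
    cl_basal: float  # L·min⁻¹·m⁻²  (fasting ISR / fasting insulin)
    cl_total: float  # L·min⁻¹·m⁻²  (ISR AUC / insulin AUC, 0-180 min)
    glucose_sensitivity: float  # pmol·min⁻¹·m⁻²·mM⁻¹ (dose-response slope)
    glucose_sensitivity_r2: float
    total_isr: float  # pmol·min⁻¹·m⁻²
    fasting_isr: float  # pmol·min⁻¹·m⁻²
    glucose_2h: float  # mg/dL

    def to_dict(self) -> dict[str, float]:
        return {
            "homa_ir": self.homa_ir,
            "matsuda_wbisi": self.matsuda_wbisi,
            "stumvoll_mcr": self.stumvoll_mcr,
            "hiri": self.hiri,
            "cl_basal": self.cl_basal,
            "cl_total": self.cl_total,
            "glucose_sensitivity": self.glucose_sensitivity,
            "glucose_sensitivity_r2": self.glucose_sensitivity_r2,
            "total_isr": self.total_isr,
            "fasting_isr": self.fasting_isr,
            "glucose_2h": self.glucose_2h,
        }


#: IndexPanel fields treated as analysis variables by the statistics layer.
PANEL_VARIABLES = (
    "homa_ir",
    "matsuda_wbisi",
    "stumvoll_mcr",
    "hiri",
    "cl_basal",
    "cl_total",
    "glucose_sensitivity",
    "total_isr",
    "glucose_2h",
)


# ---------------------------------------------------------------------------
# Primitive integrals and formulas
# ---------------------------------------------------------------------------


def auc_trapezoid(times, values, t_start: float, t_end: float) -> float:
    """Trapezoidal area under ``values`` over [t_start, t_end]; no extrapolation."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if t_start >= t_end:
        raise WindowError("t_start must precede t_end")
    if t_start < times[0] or t_end > times[-1]:
        raise WindowError("window extends beyond the sampled grid")
    mask = (times >= t_start) & (times <= t_end)
    t_in, v_in = times[mask], values[mask]
    # interpolate the window edges if they fall between samples
    if t_in.size == 0 or t_in[0] > t_start:
        t_in = np.insert(t_in, 0, t_start)
        v_in = np.insert(v_in, 0, np.interp(t_start, times, values))
    if t_in[-1] < t_end:
        t_in = np.append(t_in, t_end)
        v_in = np.append(v_in, np.interp(t_end, times, values))
    if t_in.size < 2:
        raise WindowError("fewer than 2 points in integration window")
    return float(np.trapezoid(v_in, t_in))


def homa_ir(g0: float, i0: float) -> float:
    """HOMA-IR from fasting glucose (mg/dL) and fasting insulin (pmol/L)."""
    if g0 <= 0 or i0 <= 0:
        raise DomainError("fasting glucose and insulin must be positive")
    return (g0 * (i0 / INSULIN_PMOL_PER_UU)) / 405.0


def matsuda_index(series: OGTTSeries, window: tuple[float, float] = (0.0, 120.0)) -> float:
    """Whole-body insulin sensitivity (Matsuda WBISI).

    10000 / sqrt(G0 · I0 · Ḡ · Ī) with insulin in uU/mL and glucose mg/dL;
    the mean glucose/insulin are time-weighted trapezoidal means over the
    configured window (default the classic 0-120 min formulation).
    """
    if series.times[0] != 0:
        raise InputError("Matsuda index requires a fasting (t=0) sample")
    t0, t1 = window
    post = series.times[(series.times > 0) & (series.times <= t1)]
    if post.size < 3:
        raise InputError("Matsuda index requires >=3 post-load samples")
    g0 = series.glucose[0]
    i0 = series.insulin[0] / INSULIN_PMOL_PER_UU
    g_mean = auc_trapezoid(series.times, series.glucose, t0, t1) / (t1 - t0)
    i_mean = (
        auc_trapezoid(series.times, series.insulin, t0, t1) / (t1 - t0)
    ) / INSULIN_PMOL_PER_UU
    if min(g0, i0, g_mean, i_mean) <= 0:
        raise DomainError("Matsuda index requires positive glucose and insulin")
    return 10000.0 / float(np.sqrt(g0 * i0 * g_mean * i_mean))


def hiri(series: OGTTSeries) -> float:
    """Hepatic insulin resistance index: glucose AUC(0-30) x insulin AUC(0-30).

    Requires the full early grid (0, 10, 20, 30 min); insulin stays in the
    canonical pmol/L, so values are comparable only within a consistent
    unit convention (comparisons are rank-based).
    """
    for t in (0.0, 10.0, 20.0, 30.0):
        if t not in series.times:
            raise InputError(f"HIRI undefined: missing early sample at t={t:g}")
    g_auc = auc_trapezoid(series.times, series.glucose, 0.0, 30.0)
    i_auc = auc_trapezoid(series.times, series.insulin, 0.0, 30.0)
    return g_auc * i_auc


def insulin_clearance(profile: ISRProfile, series: OGTTSeries) -> tuple[float, float]:
    """Fasting (CL0) and post-load (CL180) endogenous insulin clearance.

    CL0 = fasting ISR / fasting insulin; CL180 = ISR AUC / insulin AUC over
    the 3-hour OGTT.  With ISR in pmol·min⁻¹·m⁻² and insulin in pmol/L both
    are in L·min⁻¹·m⁻².
    """
    i0 = series.insulin[0]
    if i0 <= 0:
        raise DomainError("fasting insulin must be positive")
    span = profile.seg_minutes * profile.isr.size
    i_auc = auc_trapezoid(series.times, series.insulin, 0.0, min(span, series.times[-1]))
    if i_auc <= 0:
        raise DomainError("insulin AUC must be positive")
    cl_basal = profile.fasting_isr / i0
    cl_total = profile.isr_auc / i_auc
    return float(cl_basal), float(cl_total)


def glucose_sensitivity(profile: ISRProfile, series: OGTTSeries) -> tuple[float, float]:
    """Beta-cell glucose sensitivity: slope of the ISR-vs-glucose dose-response.

    Least-squares slope of the segment ISR against glucose (mmol/L) linearly
    interpolated to segment midpoints over the OGTT; returns (slope, R²).
    """
    mids = profile.times + profile.seg_minutes / 2.0
    mask = mids <= series.times[-1]
    g_mm = np.interp(mids[mask], series.times, series.glucose) / GLUCOSE_MGDL_PER_MM
    isr = profile.isr[mask]
    if np.ptp(g_mm) <= 0:
        raise DomainError("glucose variance is zero; dose-response slope undefined")
    res = sps.linregress(g_mm, isr)
    return float(res.slope), float(res.rvalue**2)


def stumvoll_mcr(series: OGTTSeries, subject: SubjectRecord) -> float:
    """Stumvoll metabolic clearance rate (demographic variant), mL·min⁻¹·kg⁻¹.

    18.8 - 0.271·BMI - 0.0052·I(120) [pmol/L] - 0.27·G(90) [mmol/L].
    """
    if subject.bmi is None:
        raise InputError("Stumvoll MCR requires BMI")
    try:
        i120 = series.value_at("insulin", 120.0)
        g90 = series.value_at("glucose", 90.0) / GLUCOSE_MGDL_PER_MM
    except KeyError as exc:
        raise InputError(str(exc)) from exc
    return 18.8 - 0.271 * subject.bmi - 0.0052 * i120 - 0.27 * g90


def classify_osa(ahi: float) -> OSAClass:
    """OSA severity from the apnea-hypopnea index.

    AHI <= 1: no OSA (excluded from the two-group analysis); 1 < AHI <= 5:
    mild; 5 < AHI < 10: moderate; AHI >= 10: severe.  Moderate and severe
    are analysed together.
    """
    if ahi is None or not np.isfinite(ahi) or ahi < 0:
        raise DomainError("AHI must be a finite non-negative number")
    if ahi <= 1.0:
        return OSAClass("none", "excluded")
    if ahi <= 5.0:
        return OSAClass("mild", "mild")
    if ahi < 10.0:
        return OSAClass("moderate", "moderate_severe")
    return OSAClass("severe", "moderate_severe")


def compute_index_panel(
    subject: SubjectRecord,
    series: OGTTSeries,
    profile: ISRProfile,
    matsuda_window: tuple[float, float] = (0.0, 120.0),
) -> IndexPanel:
    """Assemble the full per-subject index panel."""
    summaries = isr_summaries(profile)
    cl0, cl180 = insulin_clearance(profile, series)
    slope, r2 = glucose_sensitivity(profile, series)
    try:
        g2h = series.value_at("glucose", 120.0)
    except KeyError:
        g2h = float("nan")
    return IndexPanel(
        homa_ir=homa_ir(series.glucose[0], series.insulin[0]),
        matsuda_wbisi=matsuda_index(series, matsuda_window),
        stumvoll_mcr=stumvoll_mcr(series, subject),
        hiri=hiri(series),
        cl_basal=cl0,
        cl_total=cl180,
        glucose_sensitivity=slope,
        glucose_sensitivity_r2=r2,
        total_isr=summaries.total_isr,
        fasting_isr=summaries.fasting_isr,
        glucose_2h=g2h,
    )
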