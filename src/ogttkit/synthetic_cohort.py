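"""Synthetic OGTT cohorts with known ground truth.

The generator emulates the study population the pipeline targets: children
and adolescents with obesity, a 3-hour OGTT sampled on the canonical grid,
and nocturnal polygraphy AHI.  Its causal structure embodies the hypothesis
under test: the apnea-hypopnea index is negatively coupled to endogenous
insulin clearance, so higher AHI raises circulating insulin (and hence the
early hepatic insulin response / HIRI) at unchanged secretion.

Per subject:

* glucose excursion: gamma-shaped template G(t) = G0 + A·(t/tp)·exp(1-t/tp)
  with subject-specific baseline, amplitude and peak time;
* true secretion: ISR(t) = basal + slope·(G(t)-G0)/18 (per-mM dose-response),
  piecewise-constant on the 5-min subgrid;
* plasma C-peptide: exact forward two-compartment convolution of the true
  ISR with subject-standardized kinetics;
* plasma insulin: single post-hepatic pool dI/dt = f·S_abs/Vd - f·CL·I/Vd
  solved exactly on the subgrid, where f is hepatic first-pass survival and
  CL the subject's *effective* clearance (so that ISR/I -> CL at steady
  state, matching the ratio estimators the pipeline computes);
* assay noise: multiplicative Gaussian with per-analyte CV.

All randomness flows from one seed through named substreams so individual
components can be held fixed in tests.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .cohort_io import CANONICAL_GRID, CohortRow, CohortTable, OGTTSeries, SubjectRecord
from .cpeptide_kinetics import forward_cpeptide, standardize_params
from .errors import ConfigError
from .metabolic_indices import classify_osa

#: Substream labels -> fixed indices (seeding is positional, never by hash).
_STREAMS = {"anthropometry": 0, "ahi": 1, "curves": 2, "noise": 3}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the target cohort's shape: 36 mild / 34 moderate-severe
    OSA children with obesity, fasting glucose ~66 mg/dL, fasting insulin
    ~90-100 pmol/L, fasting C-peptide ~700 pmol/L, and a ~20% median
    clearance deficit at moderate-severe AHI via ``ahi_effect``.
    """

    n_mild: int = 36
    n_modsev: int = 34
    seed: int = 0
    # AHI: log-uniform within the class ranges (right-skewed severity)
    ahi_mild_range: tuple[float, float] = (1.0, 5.0)
    ahi_modsev_range: tuple[float, float] = (5.0, 25.0)
    # glucose excursion template (mg/dL, minutes)
    glucose_baseline: float = 66.0
    glucose_baseline_sd: float = 8.0
    glucose_peak_delta: float = 70.0  # median amplitude above baseline
    glucose_peak_cv: float = 0.20
    glucose_peak_time: float = 40.0
    glucose_peak_time_sd: float = 8.0
    # beta cell: ISR(t) = basal + slope * (G - G0)/18, between-subject CVs
    basal_isr: float = 100.0  # pmol/min/m^2
    glucose_slope: float = 140.0  # pmol/min/m^2 per mM
    beta_cell_cv: float = 0.25
    # clearance model: CL = cl_ref * exp(ahi_effect * log1p(AHI)) * subject factor
    cl_ref: float = 1.45  # L/min/m^2 effective clearance at AHI=0
    ahi_effect: float = -0.17  # per log-unit AHI, <= 0
    clearance_cv: float = 0.25
    posthepatic_fraction: float = 0.5  # hepatic first-pass survival
    insulin_vd_per_m2: float = 6.3  # L/m^2, post-hepatic insulin pool
    # assay noise (multiplicative CV)
    noise_cv_glucose: float = 0.02
    noise_cv_insulin: float = 0.05
    noise_cv_cpeptide: float = 0.04
    # anthropometry
    age_mean: float = 11.7
    age_sd: float = 2.8
    age_range: tuple[float, float] = (6.0, 18.0)
    bmi_median: float = 34.0
    bmi_cv: float = 0.10
    bmi_zscore_mean: float = 3.6
    bmi_zscore_sd: float = 0.25
    sld_prevalence: float = 0.77
    male_fraction: float = 0.45
    # grids and kinetics
    seg_minutes: float = 5.0
    grid: tuple[float, ...] = tuple(float(t) for t in CANONICAL_GRID)
    status: str = "obese"

    def validate(self) -> None:
        if self.n_mild < 0 or self.n_modsev < 0:
            raise ConfigError("subject counts must be non-negative")
        if self.n_mild + self.n_modsev == 0:
            raise ConfigError("cohort must contain at least one subject")
        if self.ahi_effect > 0:
            raise ConfigError("ahi_effect must be <= 0 (clearance cannot rise with AHI)")
        if self.ahi_mild_range[0] < 1.0 or self.ahi_mild_range[1] > 5.0:
            raise ConfigError("mild AHI range must lie within (1, 5]")
        if self.ahi_modsev_range[0] < 5.0:
            raise ConfigError("moderate-severe AHI range must lie above 5")
        if not (0 < self.posthepatic_fraction <= 1):
            raise ConfigError("posthepatic_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def ahi_effect_for_deficit(deficit: float, config: SimulationConfig | None = None) -> float:
    """``ahi_effect`` producing a given median clearance deficit in the
    moderate-severe group relative to mild (e.g. 0.20 for a 20% deficit),
    based on the median (geometric mid) AHI of each group's range."""
    cfg = config or SimulationConfig()
    med = lambda rng: math.sqrt(rng[0] * rng[1])  # median of log-uniform
    dlog = math.log1p(med(cfg.ahi_modsev_range)) - math.log1p(med(cfg.ahi_mild_range))
    return math.log(1.0 - deficit) / dlog


def subject_streams(seed: int, subject_index: int) -> dict[str, np.random.Generator]:
    """Named, independent random substreams for one subject."""
    return {
        name: np.random.default_rng(np.random.SeedSequence((seed, subject_index, idx)))
        for name, idx in _STREAMS.items()
    }


def _glucose_curve(t: np.ndarray, g0: float, amp: float, tp: float) -> np.ndarray:
    x = np.maximum(t, 0.0) / tp
    return g0 + amp * x * np.exp(1.0 - x)


def simulate_subject(
    config: SimulationConfig,
    rng_state: dict[str, np.random.Generator],
    group: str = "mild",
    subject_id: str = "S000",
):
    """Draw one subject: record, noisy OGTT series, and the truth record."""
    r_anthro = rng_state["anthropometry"]
    r_ahi = rng_state["ahi"]
    r_curve = rng_state["curves"]
    r_noise = rng_state["noise"]

    # anthropometry
    age = float(np.clip(r_anthro.normal(config.age_mean, config.age_sd), *config.age_range))
    sex = "M" if r_anthro.random() < config.male_fraction else "F"
    height = float(101.0 + 4.55 * age + r_anthro.normal(0.0, 7.0))
    bmi = float(config.bmi_median * np.exp(r_anthro.normal(0.0, config.bmi_cv)))
    weight = bmi * (height / 100.0) ** 2
    bmi_z = float(r_anthro.normal(config.bmi_zscore_mean, config.bmi_zscore_sd))
    tanner = "I" if age < 10.5 else ("II-III" if age < 13.0 else "IV-V")
    sld = bool(r_anthro.random() < config.sld_prevalence)

    # AHI: log-uniform within the group's range
    lo, hi = config.ahi_mild_range if group == "mild" else config.ahi_modsev_range
    ahi = float(np.exp(r_ahi.uniform(np.log(lo), np.log(hi))))

    record = SubjectRecord(
        subject_id=subject_id,
        age=age,
        sex=sex,
        weight=weight,
        height=height,
        ahi=ahi,
        bmi=bmi,
        bmi_zscore=bmi_z,
        tanner=tanner,
        sld=sld,
    )
    params = standardize_params(record, status=config.status)

    # smooth subject-level curve parameters
    g0 = float(max(r_curve.normal(config.glucose_baseline, config.glucose_baseline_sd), 45.0))
    amp = float(config.glucose_peak_delta * np.exp(r_curve.normal(0.0, config.glucose_peak_cv)))
    tp = float(max(r_curve.normal(config.glucose_peak_time, config.glucose_peak_time_sd), 15.0))
    basal = float(config.basal_isr * np.exp(r_curve.normal(0.0, config.beta_cell_cv)))
    slope = float(config.glucose_slope * np.exp(r_curve.normal(0.0, config.beta_cell_cv)))
    cl_subject = float(
        config.cl_ref
        * np.exp(config.ahi_effect * np.log1p(ahi))
        * np.exp(r_curve.normal(0.0, config.clearance_cv))
    )

    t_end = float(config.grid[-1])
    n_seg = int(round(t_end / config.seg_minutes))
    edges = np.arange(n_seg + 1) * config.seg_minutes
    seg_mid = edges[:-1] + config.seg_minutes / 2.0

    # true secretion per m², piecewise-constant on the subgrid
    g_smooth_mid = _glucose_curve(seg_mid, g0, amp, tp)
    isr_true = basal + slope * (g_smooth_mid - g0) / 18.0

    obs_t = np.asarray(config.grid, dtype=float)

    # C-peptide: exact forward convolution; fasting steady state at basal ISR
    c0 = basal * params.bsa / params.mcr
    cpep_clean = forward_cpeptide(
        (edges[:-1], isr_true), params, c0, obs_t, seg_minutes=config.seg_minutes
    )

    # insulin: single post-hepatic pool, exact exponential stepping
    f = config.posthepatic_fraction
    vd_i = config.insulin_vd_per_m2 * params.bsa
    cl_abs = cl_subject * params.bsa  # effective L/min
    k = f * cl_abs / vd_i
    dt = config.seg_minutes
    decay = math.exp(-k * dt)
    insulin_path = np.empty(n_seg + 1)
    insulin_path[0] = basal / cl_subject  # fasting steady state: ISR/I = CL
    u = f * isr_true * params.bsa / vd_i  # pmol/L per min forcing per segment
    for j in range(n_seg):
        insulin_path[j + 1] = insulin_path[j] * decay + (u[j] / k) * (1.0 - decay)
    ins_clean = np.interp(obs_t, edges, insulin_path)

    g_clean = _glucose_curve(obs_t, g0, amp, tp)

    def noisy(values, cv):
        if cv <= 0:
            return np.asarray(values, float)
        return np.maximum(values * (1.0 + r_noise.normal(0.0, cv, size=len(values))), 0.0)

    series = OGTTSeries(
        subject_id=subject_id,
        times=obs_t,
        glucose=noisy(g_clean, config.noise_cv_glucose),
        insulin=noisy(ins_clean, config.noise_cv_insulin),
        cpeptide=noisy(cpep_clean, config.noise_cv_cpeptide),
    )
    truth = {
        "subject_id": subject_id,
        "group": group,
        "ahi": ahi,
        "cl_subject": cl_subject,
        "basal_isr": basal,
        "glucose_slope": slope,
        "bsa": params.bsa,
        "fasting_cpeptide": c0,
        "fasting_insulin": basal / cl_subject,
        "true_total_isr": float(np.mean(isr_true)),
        "true_isr_auc": float(np.sum(isr_true) * config.seg_minutes),
    }
    return record, series, truth


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None):
    """Simulate a full cohort; returns ``(CohortTable, truth DataFrame)``."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rows: list[CohortRow] = []
    truths: list[dict] = []
    groups = ["mild"] * cfg.n_mild + ["moderate_severe"] * cfg.n_modsev
    for i, group in enumerate(groups):
        sid = f"S{i:03d}"
        streams = subject_streams(cfg.seed, i)
        record, series, truth = simulate_subject(cfg, streams, group=group, subject_id=sid)
        rows.append(
            CohortRow(record=record, series=series, osa=classify_osa(record.ahi), complete=True)
        )
        truths.append(truth)
    return CohortTable(rows), pd.DataFrame(truths)
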