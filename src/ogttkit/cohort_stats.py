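"""Cohort statistics: normality screening, two-group contrasts, point-by-point
OGTT curve comparisons, and Spearman correlations of derived indices with AHI.

Test selection mirrors small-cohort clinical practice: a Kolmogorov-Smirnov
normality screen with estimated-parameter (Lilliefors) critical values decides
between the t-test with mean±SD summaries and the Mann-Whitney U test with
median (IQR) summaries.  Categorical contrasts use Fisher's exact test when
any expected cell is below 5, else chi-square.  No multiplicity adjustment is
applied to the primary p-values (the number of tests is reported and a
Benjamini-Hochberg column is emitted as supplementary output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortTable
from .errors import AnalysisWarning, InputError

GROUPS = ("mild", "moderate_severe")
CATEGORICAL_VARIABLES = ("sex", "tanner", "sld")


@dataclass
class CohortStatsReport:
    group_table: pd.DataFrame  # per-variable center/dispersion/test/p
    curve_table: pd.DataFrame  # per-timepoint per-analyte medians/IQR/p
    corr_table: pd.DataFrame  # per-index Spearman rho/p/n vs AHI
    n_tests: int = 0


def _iqr_text(values: np.ndarray) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}-{q3:.3g})"


def _mean_sd_text(values: np.ndarray) -> str:
    return f"{np.mean(values):.3g} ± {np.std(values, ddof=1):.3g}"


def choose_test(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """Select ``t_test`` or ``mann_whitney`` by per-group normality screening.

    Each group's centered values are screened with the Lilliefors variant of
    the Kolmogorov-Smirnov test at ``alpha``; both groups normal selects the
    t-test.  Degenerate (all-equal) or tiny groups fall back to Mann-Whitney
    with a warning.
    """
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            raise InputError(f"group {name!r} has fewer than 3 values")
        if np.ptp(vals) == 0:
            warnings.warn(
                f"group {name!r} is constant; falling back to Mann-Whitney",
                AnalysisWarning,
                stacklevel=2,
            )
            return "mann_whitney"
        if vals.size < 4:
            # Lilliefors needs >=4 observations; be conservative
            return "mann_whitney"
        _, p = lilliefors(vals - np.mean(vals), dist="norm")
        if p < alpha:
            return "mann_whitney"
    return "t_test"


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, normal
    approximation with continuity correction when either group n > 20."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) > 20 or has_ties:
        method = "asymptotic"
    else:
        method = "exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _numeric_contrast(name: str, x: np.ndarray, y: np.ndarray) -> dict:
    test = choose_test({GROUPS[0]: x, GROUPS[1]: y})
    if test == "t_test":
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        s_mild, s_modsev = _mean_sd_text(x), _mean_sd_text(y)
    else:
        stat, p = mann_whitney(x, y)
        s_mild, s_modsev = _iqr_text(x), _iqr_text(y)
    return {
        "variable": name,
        "kind": "numeric",
        "mild": s_mild,
        "moderate_severe": s_modsev,
        "n_mild": int(x.size),
        "n_modsev": int(y.size),
        "test": test,
        "statistic": float(stat),
        "p": float(p),
    }


def _categorical_contrast(name: str, frame: pd.DataFrame) -> dict | None:
    sub = frame.dropna(subset=[name])
    if sub.empty or sub[name].nunique() < 2 or sub["analysis_group"].nunique() < 2:
        return None
    table = pd.crosstab(sub["analysis_group"], sub[name])
    counts = table.to_numpy()
    expected = sps.contingency.expected_freq(counts)
    if counts.shape == (2, 2) and (expected < 5).any():
        test = "fisher_exact"
        _, p = sps.fisher_exact(counts, alternative="two-sided")
        stat = float("nan")
    else:
        test = "chi_square"
        stat, p, _, _ = sps.chi2_contingency(counts)
    def fmt(group):
        if group not in table.index:
            return ""
        row = table.loc[group]
        tot = row.sum()
        return "/".join(f"{c} ({100 * c / tot:.0f}%)" for c in row)
    return {
        "variable": name,
        "kind": "categorical",
        "mild": fmt("mild"),
        "moderate_severe": fmt("moderate_severe"),
        "n_mild": int(table.loc["mild"].sum()) if "mild" in table.index else 0,
        "n_modsev": int(table.loc["moderate_severe"].sum()) if "moderate_severe" in table.index else 0,
        "test": test,
        "statistic": float(stat) if np.isfinite(stat) else float("nan"),
        "p": float(p),
    }


def compare_groups(cohort: CohortTable, variables: list[str]) -> pd.DataFrame:
    """Per-variable mild vs moderate-severe contrast table.

    Numeric variables use the normality-screened t-test / Mann-Whitney;
    categorical variables (sex, Tanner, SLD) use Fisher's exact (2x2 with any
    expected cell < 5) or chi-square.  A supplementary Benjamini-Hochberg
    column is appended; primary p-values are unadjusted.
    """
    frame = cohort.to_frame()
    frame = frame[frame["analysis_group"].isin(GROUPS)]
    if frame["analysis_group"].nunique() < 2:
        raise InputError("both analysis groups must be non-empty")
    rows = []
    for name in variables:
        if name not in frame.columns:
            raise InputError(f"variable {name!r} not present in cohort")
        if name in CATEGORICAL_VARIABLES or frame[name].dtype == object:
            row = _categorical_contrast(name, frame)
            if row is not None:
                rows.append(row)
            continue
        sub = frame.dropna(subset=[name])
        x = sub.loc[sub["analysis_group"] == "mild", name].to_numpy(float)
        y = sub.loc[sub["analysis_group"] == "moderate_severe", name].to_numpy(float)
        if x.size < 3 or y.size < 3:
            continue
        rows.append(_numeric_contrast(name, x, y))
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_bh"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def pointwise_curve_compare(cohort: CohortTable, analyte: str) -> pd.DataFrame:
    """Mann-Whitney per OGTT timepoint with per-group median (IQR).

    Timepoints with fewer than 3 subjects in either group are reported with a
    note and no p-value.  No multiplicity adjustment (the per-point design
    matches small-sample curve comparison practice; a flag column notes the
    number of tests performed).
    """
    if analyte not in ("glucose", "insulin", "cpeptide"):
        raise InputError(f"unknown analyte {analyte!r}")
    rows_by_group: dict[str, list] = {g: [] for g in GROUPS}
    for r in cohort.analysis_rows():
        rows_by_group[r.osa.analysis_group].append(r.series)
    all_times = sorted(
        {float(t) for g in GROUPS for s in rows_by_group[g] for t in s.times}
    )
    out = []
    for t in all_times:
        vals = {}
        for g in GROUPS:
            v = [
                s.value_at(analyte, t)
                for s in rows_by_group[g]
                if t in s.times
            ]
            vals[g] = np.asarray(v, float)
        row = {
            "analyte": analyte,
            "time": t,
            "n_mild": int(vals["mild"].size),
            "n_modsev": int(vals["moderate_severe"].size),
        }
        for g in GROUPS:
            if vals[g].size:
                q1, med, q3 = np.percentile(vals[g], [25, 50, 75])
                row[f"{g}_median"], row[f"{g}_q1"], row[f"{g}_q3"] = med, q1, q3
            else:
                row[f"{g}_median"] = row[f"{g}_q1"] = row[f"{g}_q3"] = np.nan
        if min(vals["mild"].size, vals["moderate_severe"].size) < 3:
            row["p"] = np.nan
            row["note"] = "skipped: fewer than 3 per group"
        else:
            _, p = mann_whitney(vals["mild"], vals["moderate_severe"])
            row["p"] = p
            row["note"] = ""
        out.append(row)
    return pd.DataFrame(out)


def spearman_vs_ahi(cohort: CohortTable, indices: list[str]) -> pd.DataFrame:
    """Spearman correlation (average ranks for ties) of each index with AHI."""
    frame = cohort.to_frame()
    frame = frame[frame["analysis_group"].isin(GROUPS)]
    rows = []
    for name in indices:
        if name not in frame.columns:
            raise InputError(f"index {name!r} not present in cohort")
        sub = frame.dropna(subset=[name, "ahi"])
        n = len(sub)
        if n < 4:
            rows.append({"index": name, "spearman_r": np.nan, "p": np.nan, "n": n,
                         "note": "fewer than 4 complete pairs"})
            continue
        vals = sub[name].to_numpy(float)
        if np.ptp(vals) == 0:
            rows.append({"index": name, "spearman_r": np.nan, "p": np.nan, "n": n,
                         "note": "constant index: correlation undefined"})
            continue
        rho, p = sps.spearmanr(sub["ahi"].to_numpy(float), vals)
        rows.append({"index": name, "spearman_r": float(rho), "p": float(p), "n": n, "note": ""})
    return pd.DataFrame(rows)


def build_report(
    cohort: CohortTable,
    variables: list[str],
    corr_indices: list[str],
    analytes: tuple[str, ...] = ("glucose", "insulin", "cpeptide"),
) -> CohortStatsReport:
    """Full statistics layer: group contrasts, curve comparisons, correlations."""
    group_table = compare_groups(cohort, variables)
    curve_parts = [pointwise_curve_compare(cohort, a) for a in analytes]
    curve_table = pd.concat(curve_parts, ignore_index=True) if curve_parts else pd.DataFrame()
    corr_table = spearman_vs_ahi(cohort, corr_indices)
    n_tests = int(len(group_table)) + int(curve_table["p"].notna().sum() if not curve_table.empty else 0) + int(
        corr_table["p"].notna().sum() if not corr_table.empty else 0
    )
    return CohortStatsReport(
        group_table=group_table,
        curve_table=curve_table,
        corr_table=corr_table,
        n_tests=n_tests,
    )
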