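"""Statistics layer: test selection, exact oracles, targeted-shift power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ogttkit import (
    CohortRow,
    CohortTable,
    OGTTSeries,
    SubjectRecord,
    choose_test,
    classify_osa,
    compare_groups,
    pointwise_curve_compare,
    spearman_vs_ahi,
)
from ogttkit.cohort_stats import mann_whitney
from ogttkit.errors import AnalysisWarning, InputError

from conftest import OBS_GRID


def _toy_cohort(values_by_group, ahis=None):
    """Cohort whose panel is replaced by a single scalar 'metric' column."""

    class FakePanel:
        def __init__(self, v):
            self.v = v

        def to_dict(self):
            return {"metric": self.v}

    rows = []
    i = 0
    for group, values in values_by_group.items():
        for v in values:
            ahi = ahis[i] if ahis is not None else (3.0 if group == "mild" else 12.0)
            rec = SubjectRecord(f"S{i}", 12.0, "M", 70.0, 150.0, ahi)
            series = OGTTSeries(
                f"S{i}", OBS_GRID, np.full(9, 90.0), np.full(9, 60.0), np.full(9, 700.0)
            )
            rows.append(CohortRow(rec, series, classify_osa(ahi), panel=FakePanel(v)))
            i += 1
    return CohortTable(rows)


# --- choose_test ----------------------------------------------------------


def test_choose_test_normal_samples_select_t_test():
    rng = np.random.default_rng(7)
    groups = {"a": rng.normal(0, 1, 200), "b": rng.normal(0.2, 1, 200)}
    assert choose_test(groups) == "t_test"


def test_choose_test_lognormal_samples_select_mann_whitney():
    rng = np.random.default_rng(7)
    groups = {"a": rng.lognormal(0, 1, 200), "b": rng.lognormal(0, 1, 200)}
    assert choose_test(groups) == "mann_whitney"


def test_choose_test_constant_group_warns_and_falls_back():
    groups = {"a": np.full(10, 3.0), "b": np.arange(10, dtype=float)}
    with pytest.warns(AnalysisWarning):
        assert choose_test(groups) == "mann_whitney"


def test_choose_test_tiny_group_rejected():
    with pytest.raises(InputError):
        choose_test({"a": np.array([1.0, 2.0]), "b": np.arange(10, dtype=float)})


# --- Mann-Whitney exactness ----------------------------------------------


def _exact_mw_p(x, y):
    """Brute-force two-sided Mann-Whitney p by enumerating all group
    assignments of the pooled sample (tie-free only)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(range(n))
    us = np.array([u_stat(c) for c in itertools.combinations(range(n + m), n)])
    lo, hi = min(u_obs, n * m - u_obs), max(u_obs, n * m - u_obs)
    return ((us >= hi).sum() + (us <= lo).sum()) / us.size


@pytest.mark.parametrize("n,m,seed", [(4, 4, 0), (5, 6, 1), (7, 8, 2), (3, 8, 3)])
def test_mann_whitney_matches_exact_enumeration(n, m, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    y = rng.normal(0.8, 1, m)
    _, p = mann_whitney(x, y)
    assert p == pytest.approx(_exact_mw_p(x, y), abs=1e-12)


def test_identical_groups_mann_whitney_p_near_one():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    cohort = _toy_cohort({"mild": vals, "moderate_severe": vals})
    table = compare_groups(cohort, ["metric"])
    row = table[table["variable"] == "metric"].iloc[0]
    assert row["p"] > 0.9


# --- compare_groups -------------------------------------------------------


def test_fisher_p_matches_hypergeometric_hand_computation():
    """2x2 table (20,16 / 11,23): two-sided Fisher p from the hypergeometric
    distribution summed over tables as or less probable than observed."""
    table = np.array([[20, 16], [11, 23]])
    _, p_scipy = sps.fisher_exact(table)
    # hand computation: X ~ Hypergeom(N=70, K=31 row-1 total, n=36 col-1 total)
    N, K, n = 70, 31, 36
    pmf_obs = sps.hypergeom.pmf(20, N, K, n)
    ks = np.arange(max(0, n + K - N), min(K, n) + 1)
    pmf = sps.hypergeom.pmf(ks, N, K, n)
    p_hand = pmf[pmf <= pmf_obs * (1 + 1e-12)].sum()
    assert p_scipy == pytest.approx(p_hand, abs=1e-10)


def test_compare_groups_categorical_uses_fisher_for_sparse_cells():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=14)
    cohort = _toy_cohort({"mild": vals[:7], "moderate_severe": vals[7:]})
    for i, row in enumerate(cohort.rows):
        row.record.sld = i % 7 == 0  # sparse positives -> expected cells < 5
    table = compare_groups(cohort, ["sld", "metric"])
    sld_row = table[table["variable"] == "sld"].iloc[0]
    assert sld_row["test"] == "fisher_exact"
    assert 0.0 <= sld_row["p"] <= 1.0


def test_compare_groups_unknown_variable_named():
    cohort = _toy_cohort({"mild": np.arange(5.0), "moderate_severe": np.arange(5.0)})
    with pytest.raises(InputError, match="nope"):
        compare_groups(cohort, ["nope"])


def test_compare_groups_reports_bh_column():
    rng = np.random.default_rng(11)
    cohort = _toy_cohort(
        {"mild": rng.normal(0, 1, 10), "moderate_severe": rng.normal(2, 1, 10)}
    )
    table = compare_groups(cohort, ["metric", "age"])
    assert "p_bh" in table.columns
    assert (table["p_bh"] >= table["p"] - 1e-12).all()


# --- pointwise curves -----------------------------------------------------


def _curve_cohort(rng, n_per_group=12, shift_time=None, shift_factor=1.5):
    rows = []
    i = 0
    for group, ahi in (("mild", 3.0), ("moderate_severe", 12.0)):
        for _ in range(n_per_group):
            ins = 100 + 40 * np.exp(-0.5 * ((OBS_GRID - 60) / 40.0) ** 2)
            ins = ins * np.exp(rng.normal(0, 0.15, ins.size))
            if group == "moderate_severe" and shift_time is not None:
                ins[OBS_GRID == shift_time] *= shift_factor
            rec = SubjectRecord(f"C{i}", 12.0, "M", 70.0, 150.0, ahi)
            series = OGTTSeries(
                f"C{i}", OBS_GRID, np.full(9, 100.0), ins, np.full(9, 700.0)
            )
            rows.append(CohortRow(rec, series, classify_osa(ahi)))
            i += 1
    return CohortTable(rows)


def test_pointwise_identical_groups_null_ps():
    rng = np.random.default_rng(0)
    cohort = _curve_cohort(np.random.default_rng(5))
    # copy mild values into moderate_severe -> identical distributions pointwise
    mild = [r for r in cohort if r.osa.analysis_group == "mild"]
    for r, src in zip([r for r in cohort if r.osa.analysis_group == "moderate_severe"], mild):
        r.series.insulin = src.series.insulin.copy()
    table = pointwise_curve_compare(cohort, "insulin")
    assert (table["p"] > 0.9).all()


def test_pointwise_shape_one_row_per_gridpoint():
    cohort = _curve_cohort(np.random.default_rng(1))
    table = pointwise_curve_compare(cohort, "glucose")
    assert len(table) == OBS_GRID.size
    assert set(table["time"]) == set(OBS_GRID.tolist())


def test_pointwise_targeted_shift_found_at_t60():
    """Insulin +50% at t=60 only: the minimum-p timepoint is t=60 in the
    median over 50 seeded replicates."""
    argmins = []
    for rep in range(50):
        rng = np.random.default_rng(1000 + rep)
        cohort = _curve_cohort(rng, shift_time=60.0)
        table = pointwise_curve_compare(cohort, "insulin")
        argmins.append(float(table.loc[table["p"].idxmin(), "time"]))
    assert np.median(argmins) == pytest.approx(60.0)


def test_pointwise_small_groups_skipped_with_note():
    cohort = _curve_cohort(np.random.default_rng(2), n_per_group=2)
    table = pointwise_curve_compare(cohort, "insulin")
    assert table["p"].isna().all()
    assert (table["note"].str.contains("fewer than 3")).all()


# --- Spearman vs AHI ------------------------------------------------------


def test_spearman_monotone_extremes():
    ahis = np.array([2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 15.0, 20.0])
    up = _toy_cohort(
        {"mild": ahis[:3] * 10, "moderate_severe": ahis[3:] * 10}, ahis=ahis
    )
    table = spearman_vs_ahi(up, ["metric"])
    assert table["spearman_r"].iloc[0] == pytest.approx(1.0)
    down = _toy_cohort(
        {"mild": -ahis[:3], "moderate_severe": -ahis[3:]}, ahis=ahis
    )
    table = spearman_vs_ahi(down, ["metric"])
    assert table["spearman_r"].iloc[0] == pytest.approx(-1.0)


def test_spearman_tie_handling_hand_oracle():
    """5 pairs with one tie: rho equals the average-rank formula by hand."""
    ahis = np.array([2.0, 3.0, 4.0, 6.0, 8.0])
    vals = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
    cohort = _toy_cohort({"mild": vals[:3], "moderate_severe": vals[3:]}, ahis=ahis)
    # hand ranks: ahi -> 1..5; vals -> [1, 2.5, 2.5, 4, 5]; Pearson of ranks
    rx = np.array([1, 2, 3, 4, 5.0])
    ry = np.array([1, 2.5, 2.5, 4, 5.0])
    hand = np.corrcoef(rx, ry)[0, 1]
    table = spearman_vs_ahi(cohort, ["metric"])
    assert table["spearman_r"].iloc[0] == pytest.approx(hand, rel=1e-12)


def test_spearman_constant_index_flagged_not_fatal():
    cohort = _toy_cohort(
        {"mild": np.full(4, 5.0), "moderate_severe": np.full(4, 5.0)},
        ahis=np.array([2.0, 3.0, 4.0, 4.5, 6.0, 8.0, 12.0, 20.0]),
    )
    table = spearman_vs_ahi(cohort, ["metric"])
    assert np.isnan(table["spearman_r"].iloc[0])
    assert "undefined" in table["note"].iloc[0]
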