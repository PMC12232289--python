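"""Domain types, unit conventions, and tabular readers/writers.

Canonical units throughout the package: glucose mg/dL, insulin pmol/L,
C-peptide pmol/L, time minutes since the oral glucose load.  Conversion
constants: 1 uU/mL insulin = 6.0 pmol/L; 1 mmol/L glucose = 18.0 mg/dL;
1 nmol/L C-peptide = 1000 pmol/L.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IntegrityError,
    ParseError,
    SchemaError,
    UnitSuspicionWarning,
)

#: Sampling grid of the 3-hour OGTT: every 10 min for the first 30 min,
#: then every 30 min out to 180 min.
CANONICAL_GRID: tuple[int, ...] = (0, 10, 20, 30, 60, 90, 120, 150, 180)

#: Multiplicative factors mapping a declared input unit to the canonical unit.
UNIT_FACTORS: dict[str, dict[str, float]] = {
    "glucose": {"mg/dL": 1.0, "mmol/L": 18.0},
    "insulin": {"pmol/L": 1.0, "uU/mL": 6.0, "uIU/mL": 6.0, "mU/L": 6.0},
    "cpeptide": {"pmol/L": 1.0, "nmol/L": 1000.0},
}

#: Fasting C-peptide below this (pmol/L) is dimensionally suspect and
#: triggers a unit-suspicion warning (plausible nmol/L mislabelling).
CPEPTIDE_SUSPICION_PMOL_L = 30.0

TANNER_STAGES = ("I", "II-III", "IV-V")


def convert_unit(values: np.ndarray, analyte: str, unit: str) -> np.ndarray:
    """Convert ``values`` of ``analyte`` from ``unit`` to the canonical unit."""
    try:
        factor = UNIT_FACTORS[analyte][unit]
    except KeyError as exc:
        raise SchemaError(f"unknown unit {unit!r} for analyte {analyte!r}") from exc
    return np.asarray(values, dtype=float) * factor


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OGTTSeries:
    """One subject's sampled glucose/insulin/C-peptide trajectories.

    ``times`` must be strictly increasing and start at 0; the three analyte
    series are aligned with ``times`` and hold canonical units.
    """

    subject_id: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    cpeptide: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        self.cpeptide = np.asarray(self.cpeptide, dtype=float)
        for v in self.violations():
            raise ValueError(f"{self.subject_id}: {v}")

    def violations(self) -> list[str]:
        """Invariant violations as human-readable strings (empty if valid)."""
        out: list[str] = []
        n = len(self.times)
        if not (len(self.glucose) == len(self.insulin) == len(self.cpeptide) == n):
            out.append("series lengths differ")
            return out
        if n == 0:
            out.append("empty series")
            return out
        if self.times[0] != 0:
            out.append("first time must be 0")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            out.append("times not strictly increasing")
        for name in ("glucose", "insulin", "cpeptide"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                out.append(f"{name} contains non-finite values")
            elif np.any(arr < 0):
                out.append(f"{name} contains negative values")
        if n < 5:
            out.append("fewer than 5 timepoints")
        return out

    @property
    def grid_status(self) -> str:
        """Relation of ``times`` to the canonical OGTT grid."""
        have = set(self.times.tolist())
        canonical = set(float(t) for t in CANONICAL_GRID)
        if have == canonical:
            return "canonical"
        if have < canonical:
            return "subset"
        if have > canonical:
            return "superset"
        return "other"

    @property
    def complete(self) -> bool:
        return self.grid_status == "canonical"

    def value_at(self, analyte: str, t: float) -> float:
        """Sampled value of ``analyte`` exactly at time ``t`` (no interpolation)."""
        idx = np.nonzero(self.times == t)[0]
        if idx.size == 0:
            raise KeyError(f"{self.subject_id}: no sample at t={t}")
        return float(getattr(self, analyte)[idx[0]])


@dataclass
class SubjectRecord:
    """Demographics, anthropometry and sleep-study summary for one subject."""

    subject_id: str
    age: float  # years
    sex: str  # "M" | "F"
    weight: float  # kg
    height: float  # cm
    ahi: float  # events/hour
    bmi: float | None = None  # kg/m^2; derived from weight/height if absent
    bmi_zscore: float | None = None
    tanner: str | None = None  # "I" | "II-III" | "IV-V"
    sld: bool | None = None
    lipids: dict[str, float] = field(default_factory=dict)  # mg/dL

    def __post_init__(self) -> None:
        if self.bmi is None and self.weight and self.height:
            self.bmi = self.weight / (self.height / 100.0) ** 2

    def violations(self) -> list[str]:
        out: list[str] = []
        if not self.weight or self.weight <= 0:
            out.append("weight > 0 violated")
        if not self.height or self.height <= 0:
            out.append("height > 0 violated")
        if self.ahi is None or self.ahi < 0 or not np.isfinite(self.ahi):
            out.append("ahi >= 0 violated")
        if self.sex not in ("M", "F"):
            out.append("sex must be M or F")
        if self.tanner is not None and self.tanner not in TANNER_STAGES:
            out.append(f"tanner must be one of {TANNER_STAGES}")
        if (
            self.bmi is not None
            and self.weight
            and self.height
            and self.weight > 0
            and self.height > 0
        ):
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(self.bmi - implied) > 0.05 * implied:
                out.append("bmi inconsistent with weight/height (>5%)")
        return out


@dataclass(frozen=True)
class OSAClass:
    """Severity label from the apnea-hypopnea index plus the two-group
    analysis assignment (moderate and severe are analysed together)."""

    label: str  # none | mild | moderate | severe
    analysis_group: str  # mild | moderate_severe | excluded

    def __post_init__(self) -> None:
        if (self.label == "none") != (self.analysis_group == "excluded"):
            raise ValueError("label=none must pair with analysis_group=excluded")
        if self.label in ("moderate", "severe") and self.analysis_group != "moderate_severe":
            raise ValueError("moderate/severe must map to moderate_severe")
        if self.label == "mild" and self.analysis_group != "mild":
            raise ValueError("mild must map to analysis_group=mild")


@dataclass
class CohortRow:
    record: SubjectRecord
    series: OGTTSeries
    osa: OSAClass
    panel: "object | None" = None  # IndexPanel once computed
    complete: bool = True


class CohortTable:
    """Validated collection of subjects; the unit of the statistics layer.

    Subject ids are unique and every row's OSA class is derived from its AHI.
    """

    def __init__(self, rows: Iterable[CohortRow]):
        from .metabolic_indices import classify_osa  # deferred: avoids cycle

        self.rows: list[CohortRow] = list(rows)
        ids = [r.record.subject_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate subject_id(s): {dupes}")
        for r in self.rows:
            expected = classify_osa(r.record.ahi)
            if r.osa != expected:
                raise IntegrityError(
                    f"{r.record.subject_id}: OSA class {r.osa} does not derive "
                    f"from ahi={r.record.ahi}"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def subject_ids(self) -> list[str]:
        return [r.record.subject_id for r in self.rows]

    def get(self, subject_id: str) -> CohortRow:
        for r in self.rows:
            if r.record.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    def analysis_rows(self) -> list[CohortRow]:
        """Rows belonging to one of the two analysis groups."""
        return [r for r in self.rows if r.osa.analysis_group != "excluded"]

    def to_frame(self) -> pd.DataFrame:
        """Flat per-subject frame: demographics, AHI, OSA class, indices."""
        recs = []
        for r in self.rows:
            d = {
                "subject_id": r.record.subject_id,
                "age": r.record.age,
                "sex": r.record.sex,
                "weight": r.record.weight,
                "height": r.record.height,
                "bmi": r.record.bmi,
                "bmi_zscore": r.record.bmi_zscore,
                "tanner": r.record.tanner,
                "sld": r.record.sld,
                "ahi": r.record.ahi,
                "osa_label": r.osa.label,
                "analysis_group": r.osa.analysis_group,
                "complete": r.complete,
            }
            for k, v in r.record.lipids.items():
                d[k] = v
            if r.panel is not None:
                d.update(r.panel.to_dict())
            recs.append(d)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

DEMOGRAPHIC_COLUMNS = {
    "subject_id": "subject_id",
    "age": "age",
    "sex": "sex",
    "weight": "weight",
    "height": "height",
    "ahi": "ahi",
    "bmi": "bmi",
    "bmi_zscore": "bmi_zscore",
    "tanner": "tanner",
    "sld": "sld",
}

MANDATORY = ("subject_id", "age", "sex", "weight", "height", "ahi")


def default_schema() -> dict:
    """Schema describing the package's own wide CSV dialect."""
    return {
        "format": "wide",
        "units": {"glucose": "mg/dL", "insulin": "pmol/L", "cpeptide": "pmol/L"},
        "times": list(CANONICAL_GRID),
        "prefixes": {"glucose": "g", "insulin": "i", "cpeptide": "c"},
        "columns": dict(DEMOGRAPHIC_COLUMNS),
    }


def _merge_schema(schema: Mapping | None) -> dict:
    base = default_schema()
    if schema:
        for key, val in schema.items():
            if isinstance(val, Mapping) and key in base and isinstance(base[key], dict):
                base[key] = {**base[key], **val}
            else:
                base[key] = val
    return base


def _to_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(f"non-numeric value {raw.iloc[row]!r} in column {col!r}, row {row}")
    return num


def _parse_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    if s in ("", "nan", "na"):
        return None
    raise ParseError(f"cannot parse boolean {v!r}")


def read_cohort(path: str | Path, schema: Mapping | None = None):
    """Read a delimited-text cohort file into a validated :class:`CohortTable`.

    Returns ``(cohort, rejects)`` where ``rejects`` is a DataFrame of rows
    that failed an invariant (subject_id, reason); invalid rows are reported,
    never silently dropped.
    """
    from .metabolic_indices import classify_osa  # deferred: avoids cycle

    sch = _merge_schema(schema)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={sch["columns"]["subject_id"]: str})

    cols = sch["columns"]
    for key in MANDATORY:
        if cols.get(key) not in df.columns:
            raise SchemaError(f"missing mandatory column {cols.get(key, key)!r} (field {key})")

    fmt = sch.get("format", "wide")
    if fmt == "wide":
        subjects = _read_wide(df, sch)
    elif fmt == "long":
        subjects = _read_long(df, sch)
    else:
        raise SchemaError(f"unknown format {fmt!r}")

    rows: list[CohortRow] = []
    rejects: list[dict] = []
    for record, times, gl, ins, cp in subjects:
        reasons = record.violations()
        series = None
        if not reasons:
            series = OGTTSeries.__new__(OGTTSeries)
            series.subject_id = record.subject_id
            series.times = np.asarray(times, dtype=float)
            series.glucose = np.asarray(gl, dtype=float)
            series.insulin = np.asarray(ins, dtype=float)
            series.cpeptide = np.asarray(cp, dtype=float)
            reasons = series.violations()
        if reasons:
            for reason in reasons:
                rejects.append({"subject_id": record.subject_id, "reason": reason})
            continue
        if series.cpeptide[0] < CPEPTIDE_SUSPICION_PMOL_L:
            warnings.warn(
                f"{record.subject_id}: fasting C-peptide {series.cpeptide[0]:.3g} pmol/L "
                "is dimensionally suspect (nmol/L mislabelling?)",
                UnitSuspicionWarning,
                stacklevel=2,
            )
        rows.append(
            CohortRow(
                record=record,
                series=series,
                osa=classify_osa(record.ahi),
                complete=series.complete,
            )
        )
    rejects_df = pd.DataFrame(rejects, columns=["subject_id", "reason"])
    return CohortTable(rows), rejects_df


def _read_record(df_row: pd.Series, sch: Mapping, numeric: Mapping) -> SubjectRecord:
    cols = sch["columns"]

    def col(key):
        name = cols.get(key)
        return name if name in df_row.index else None

    def num(key):
        name = col(key)
        if name is None:
            return None
        v = numeric[name].loc[df_row.name]
        return None if pd.isna(v) else float(v)

    tanner = None
    if col("tanner") is not None:
        t = df_row[col("tanner")]
        tanner = None if pd.isna(t) else str(t)
    sld = _parse_bool(df_row[col("sld")]) if col("sld") is not None else None
    lipids = {}
    for lip in ("cholesterol", "hdl", "triglycerides"):
        if lip in df_row.index and not pd.isna(df_row[lip]):
            lipids[lip] = float(df_row[lip])
    return SubjectRecord(
        subject_id=str(df_row[cols["subject_id"]]),
        age=num("age"),
        sex=str(df_row[cols["sex"]]).strip(),
        weight=num("weight"),
        height=num("height"),
        ahi=num("ahi"),
        bmi=num("bmi"),
        bmi_zscore=num("bmi_zscore"),
        tanner=tanner,
        sld=sld,
        lipids=lipids,
    )


def _numeric_table(df: pd.DataFrame, names: Sequence[str]) -> dict[str, pd.Series]:
    return {name: _to_numeric(df, name) for name in names if name in df.columns}


def _read_wide(df: pd.DataFrame, sch: Mapping):
    cols = sch["columns"]
    if df[cols["subject_id"]].duplicated().any():
        dupes = df[cols["subject_id"]][df[cols["subject_id"]].duplicated()].tolist()
        raise IntegrityError(f"duplicate subject rows: {dupes}")
    times = [float(t) for t in sch["times"]]
    prefixes = sch["prefixes"]
    units = sch["units"]
    analyte_cols = {
        a: [f"{prefixes[a]}{int(t)}" for t in times] for a in ("glucose", "insulin", "cpeptide")
    }
    numeric_names = [c for group in analyte_cols.values() for c in group if c in df.columns]
    numeric_names += [
        cols[k] for k in ("age", "weight", "height", "ahi", "bmi", "bmi_zscore")
        if cols.get(k) in df.columns
    ]
    numeric = _numeric_table(df, numeric_names)

    out = []
    for _, df_row in df.iterrows():
        record = _read_record(df_row, sch, numeric)
        t_keep, gl, ins, cp = [], [], [], []
        for t in times:
            vals = {}
            ok = True
            for a in ("glucose", "insulin", "cpeptide"):
                name = f"{prefixes[a]}{int(t)}"
                if name not in df.columns or pd.isna(numeric[name].loc[df_row.name]):
                    ok = False
                    break
                vals[a] = float(numeric[name].loc[df_row.name])
            if ok:
                t_keep.append(t)
                gl.append(convert_unit(vals["glucose"], "glucose", units["glucose"]))
                ins.append(convert_unit(vals["insulin"], "insulin", units["insulin"]))
                cp.append(convert_unit(vals["cpeptide"], "cpeptide", units["cpeptide"]))
        out.append((record, t_keep, np.asarray(gl, float), np.asarray(ins, float), np.asarray(cp, float)))
    return out


def _read_long(df: pd.DataFrame, sch: Mapping):
    cols = sch["columns"]
    units = sch["units"]
    for needed in ("time", "glucose", "insulin", "cpeptide"):
        name = cols.get(needed, needed)
        if name not in df.columns:
            raise SchemaError(f"missing mandatory column {name!r} (field {needed})")
    tcol = cols.get("time", "time")
    sid = cols["subject_id"]
    if df.duplicated(subset=[sid, tcol]).any():
        dupes = df.loc[df.duplicated(subset=[sid, tcol]), [sid, tcol]].values.tolist()
        raise IntegrityError(f"duplicate (subject, time) rows: {dupes}")
    numeric_names = [tcol] + [cols.get(a, a) for a in ("glucose", "insulin", "cpeptide")]
    numeric_names += [
        cols[k] for k in ("age", "weight", "height", "ahi", "bmi", "bmi_zscore")
        if cols.get(k) in df.columns
    ]
    numeric = _numeric_table(df, numeric_names)

    out = []
    for _, grp in df.groupby(sid, sort=False):
        grp = grp.sort_values(tcol, key=lambda s: pd.to_numeric(s))
        record = _read_record(grp.iloc[0], sch, numeric)
        t = numeric[tcol].loc[grp.index].to_numpy(float)
        gl = convert_unit(
            numeric[cols.get("glucose", "glucose")].loc[grp.index].to_numpy(float),
            "glucose", units["glucose"],
        )
        ins = convert_unit(
            numeric[cols.get("insulin", "insulin")].loc[grp.index].to_numpy(float),
            "insulin", units["insulin"],
        )
        cp = convert_unit(
            numeric[cols.get("cpeptide", "cpeptide")].loc[grp.index].to_numpy(float),
            "cpeptide", units["cpeptide"],
        )
        out.append((record, t, gl, ins, cp))
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort in the package's wide CSV dialect (canonical units)."""
    path = Path(path)
    recs = []
    for r in cohort:
        d = {
            "subject_id": r.record.subject_id,
            "age": r.record.age,
            "sex": r.record.sex,
            "weight": r.record.weight,
            "height": r.record.height,
            "bmi": r.record.bmi,
            "bmi_zscore": r.record.bmi_zscore,
            "tanner": r.record.tanner,
            "sld": r.record.sld,
            "ahi": r.record.ahi,
        }
        for prefix, analyte in (("g", "glucose"), ("i", "insulin"), ("c", "cpeptide")):
            arr = getattr(r.series, analyte)
            for t, v in zip(r.series.times, arr):
                d[f"{prefix}{int(t)}"] = repr(float(v))
        recs.append(d)
    pd.DataFrame(recs).to_csv(path, index=False)


def config_hash(config: Mapping) -> str:
    """Stable SHA-256 of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(
    cohort: CohortTable,
    stats,  # CohortStatsReport | None
    outdir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    extra_tables: Mapping[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write the per-subject index table, the group/curve/correlation tables
    and a machine-readable run log.  Returns the paths written."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    idx_path = outdir / "indices.csv"
    cohort.to_frame().to_csv(idx_path, index=False)
    written["indices"] = idx_path

    if stats is not None:
        for name, table in (
            ("group_table", stats.group_table),
            ("curve_table", stats.curve_table),
            ("corr_table", stats.corr_table),
        ):
            p = outdir / f"{name}.csv"
            table.to_csv(p, index=False)
            written[name] = p

    if extra_tables:
        for name, table in extra_tables.items():
            p = outdir / f"{name}.csv"
            table.to_csv(p, index=False)
            written[name] = p

    log = {
        "package_version": __version__,
        "seed": seed,
        "n_subjects": len(cohort),
        "config_hash": config_hash(config) if config is not None else None,
        "config": config,
        "files": sorted(str(p.name) for p in written.values()),
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    written["run_log"] = log_path
    return written
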