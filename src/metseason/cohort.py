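"""Synthetic health-checkup cohort with known seasonal structure.

Emulates a per-visit record table from an annual screening programme for
adults aged 40–74 (one checkup per person per Japanese fiscal year, April
through March).  Each metabolic marker is generated additively as

    value = trend(t) + seasonal_offset(calendar month) + Gaussian noise,

with the twelve seasonal offsets constrained to sum to zero, so every
downstream stage — filtering, classification, monthly aggregation and
seasonal-trend decomposition — has an exact ground truth to recover.

Real checkup tables carry recurring data-quality problems; the generator
plants them at configurable rates and records every planted instance in an
:class:`ArtifactManifest`:

* duplicate records for the same person within a fiscal year,
* subjects on medication for diabetes/hypertension/dyslipidemia, or with
  the medication self-report missing,
* sentinel measurement values (literal ``0`` or ``9.999``),
* gross outliers (true value times ten).

Subjects keep a stable preferred checkup month across years (drawn once
per subject, with occasional one-month jitter), mirroring the tendency of
people to book their checkup at the same time every year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .stl import MonthlySeries

__all__ = [
    "MARKERS",
    "MARKER_COLUMNS",
    "MarkerModel",
    "SeasonalModelSpec",
    "ArtifactManifest",
    "generate_cohort",
    "true_monthly_series",
    "write_cohort",
    "read_cohort",
]

#: canonical marker names, in conventional reporting order
MARKERS = ("wc", "sbp", "dbp", "tg", "hdlc", "fpg")

#: marker -> column holding the (resolved) measurement
MARKER_COLUMNS = {
    "wc": "wc_cm",
    "sbp": "sbp_mmhg",
    "dbp": "dbp_mmhg",
    "tg": "tg_mgdl",
    "hdlc": "hdlc_mgdl",
    "fpg": "fpg_mgdl",
}

#: fraction of visits where the first BP reading failed and only the
#: second is usable (a fixed feature of the data shape, not an artifact)
_BP_RETEST_RATE = 0.02
#: per-visit probability of shifting one month off the preferred month
_MONTH_JITTER_RATE = 0.2
#: fraction of medication-affected subjects whose report is missing
#: rather than "yes"
_MISSING_REPORT_SHARE = 0.25


def _cosine_offsets(amplitude: float, peak_month: int = 1) -> tuple[float, ...]:
    """Zero-sum 12-month pattern with the given peak-to-trough amplitude."""
    m = np.arange(1, 13)
    s = 0.5 * amplitude * np.cos(2 * np.pi * (m - peak_month) / 12.0)
    return tuple(np.round(s - s.mean(), 6))


@dataclass(frozen=True)
class MarkerModel:
    """Generative model for one marker: linear trend + monthly offsets + noise."""

    intercept: float
    slope: float  # units per month
    seasonal_offsets: tuple[float, ...]
    noise_sd: float

    def trend_at(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def _default_markers() -> dict[str, MarkerModel]:
    # Intercepts near sex-pooled medians of Japanese checkup populations;
    # seasonal amplitudes of the order reported for these markers (winter
    # peak for all but TG/HDL-C direction handled by sign of amplitude use).
    return {
        "wc": MarkerModel(80.5, 0.0, _cosine_offsets(0.5, peak_month=1), 8.0),
        "sbp": MarkerModel(126.0, -0.01, _cosine_offsets(4.0, peak_month=1), 16.0),
        "dbp": MarkerModel(74.0, 0.0, _cosine_offsets(2.7, peak_month=1), 11.0),
        "tg": MarkerModel(95.0, 0.0, _cosine_offsets(9.5, peak_month=8), 45.0),
        "hdlc": MarkerModel(62.0, 0.0, _cosine_offsets(4.3, peak_month=1), 16.0),
        "fpg": MarkerModel(92.0, 0.01, _cosine_offsets(1.5, peak_month=1), 9.0),
    }


@dataclass(frozen=True)
class SeasonalModelSpec:
    """Ground-truth parameters for a synthetic checkup cohort.

    The default window (April 2012 – December 2017, 69 months) matches a
    five-year-nine-month observation span starting at a fiscal-year
    boundary; the default artifact rates reflect the orders of magnitude
    seen in population checkup databases (duplicates are rare; medication
    or a missing medication self-report affects a large minority of an
    elderly-skewed insured population).
    """

    markers: dict[str, MarkerModel] = field(default_factory=_default_markers)
    n_subjects: int = 5000
    window: tuple[tuple[int, int], tuple[int, int]] = ((2012, 4), (2017, 12))
    sex_ratio: float = 0.42  # fraction male
    age_range: tuple[float, float] = (40.0, 74.0)
    visit_month_weights: tuple[float, ...] = (1.0,) * 12
    dup_rate: float = 0.0025
    medicated_rate: float = 0.44
    sentinel_rate: float = 0.001
    gross_outlier_rate: float = 2e-5
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name, model in self.markers.items():
            if name not in MARKERS:
                raise ValueError(f"markers: unknown marker {name!r}")
            if len(model.seasonal_offsets) != 12:
                raise ValueError(f"markers[{name}].seasonal_offsets must have 12 values")
            if abs(sum(model.seasonal_offsets)) > 1e-6:
                raise ValueError(f"markers[{name}].seasonal_offsets must sum to 0")
            if model.noise_sd <= 0:
                raise ValueError(f"markers[{name}].noise_sd must be > 0")
        for name in MARKERS:
            if name not in self.markers:
                raise ValueError(f"markers: missing model for {name!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] < 0:
            raise ValueError("age_range must be an increasing pair of non-negative years")
        if len(self.visit_month_weights) != 12:
            raise ValueError("visit_month_weights must have 12 entries")
        if any(w < 0 for w in self.visit_month_weights):
            raise ValueError("visit_month_weights must be non-negative")
        if sum(self.visit_month_weights) <= 0:
            raise ValueError("visit_month_weights must not all be zero")
        for rate_name in ("dup_rate", "medicated_rate", "sentinel_rate", "gross_outlier_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1], got {rate}")
        if self.n_months < 24:
            raise ValueError("window must span at least two full years (24 months)")

    # -- window helpers -----------------------------------------------------

    @property
    def start_period(self) -> pd.Period:
        y, m = self.window[0]
        return pd.Period(year=y, month=m, freq="M")

    @property
    def end_period(self) -> pd.Period:
        y, m = self.window[1]
        return pd.Period(year=y, month=m, freq="M")

    @property
    def n_months(self) -> int:
        return (self.end_period - self.start_period).n + 1

    def month_index(self, year, month) -> np.ndarray:
        """Months elapsed since the window start (the trend's time axis)."""
        return (np.asarray(year) - self.window[0][0]) * 12 + (
            np.asarray(month) - self.window[0][1]
        )


@dataclass
class ArtifactManifest:
    """Record identifiers of every planted data-quality artifact."""

    duplicates: list[int] = field(default_factory=list)
    medicated_records: list[int] = field(default_factory=list)
    missing_report_records: list[int] = field(default_factory=list)
    sentinels: list[tuple[int, str]] = field(default_factory=list)
    gross_outliers: list[tuple[int, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "duplicates": len(self.duplicates),
            "medicated_records": len(self.medicated_records),
            "missing_report_records": len(self.missing_report_records),
            "sentinels": len(self.sentinels),
            "gross_outliers": len(self.gross_outliers),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {"counts": self.counts, **asdict(self)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArtifactManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            duplicates=list(payload["duplicates"]),
            medicated_records=list(payload["medicated_records"]),
            missing_report_records=list(payload["missing_report_records"]),
            sentinels=[tuple(x) for x in payload["sentinels"]],
            gross_outliers=[tuple(x) for x in payload["gross_outliers"]],
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def true_monthly_series(spec: SeasonalModelSpec, marker: str) -> MonthlySeries:
    """Noise-free monthly target for one marker: trend(t) + offset(month)."""
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    model = spec.markers[marker]
    periods = pd.period_range(spec.start_period, spec.end_period, freq="M")
    t = np.arange(len(periods), dtype=float)
    offsets = np.asarray(model.seasonal_offsets)[np.asarray(periods.month) - 1]
    return MonthlySeries(start=spec.window[0], values=model.trend_at(t) + offsets)


def _fiscal_year(year: np.ndarray, month: np.ndarray) -> np.ndarray:
    return np.asarray(year) - (np.asarray(month) < 4)


def generate_cohort(spec: SeasonalModelSpec) -> tuple[pd.DataFrame, ArtifactManifest]:
    """Generate the record table and the manifest of planted artifacts.

    Deterministic for a given ``spec.seed``: all randomness flows through a
    single generator, and artifacts are planted in a fixed order
    (duplicates, medication, sentinels, gross outliers) on disjoint
    targets so each preprocessing stage has an unambiguous ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    (start_y, start_m), (end_y, end_m) = spec.window

    subject_id = np.arange(1, n + 1)
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    age0 = rng.uniform(*spec.age_range, size=n)
    start_date = spec.start_period.to_timestamp()
    birth_date = start_date - pd.to_timedelta(
        np.round(age0 * 365.25 + rng.uniform(0, 365, size=n)), unit="D"
    )
    weights = np.asarray(spec.visit_month_weights, dtype=float)
    preferred_month = rng.choice(np.arange(1, 13), size=n, p=weights / weights.sum())

    fy_first = start_y - (start_m < 4)
    fy_last = end_y - (end_m < 4)

    rows: list[pd.DataFrame] = []
    for fy in range(fy_first, fy_last + 1):
        jitter = rng.choice(
            [-1, 0, 1], size=n, p=[_MONTH_JITTER_RATE / 2, 1 - _MONTH_JITTER_RATE, _MONTH_JITTER_RATE / 2]
        )
        month = (preferred_month - 1 + jitter) % 12 + 1
        year = np.where(month >= 4, fy, fy + 1)
        day = rng.integers(1, 29, size=n)
        # keep visits inside the observation window
        ok = (year * 12 + month >= start_y * 12 + start_m) & (
            year * 12 + month <= end_y * 12 + end_m
        )
        frame = pd.DataFrame(
            {
                "subject_id": subject_id[ok],
                "sex": sex[ok],
                "birth_date": birth_date[ok],
                "visit_year": year[ok],
                "visit_month": month[ok],
                "visit_day": day[ok],
            }
        )
        rows.append(frame)
    visits = pd.concat(rows, ignore_index=True)
    visits = visits.sort_values(["subject_id", "visit_year", "visit_month"], kind="stable")
    visits = visits.reset_index(drop=True)

    m = len(visits)
    t_idx = spec.month_index(visits["visit_year"].to_numpy(), visits["visit_month"].to_numpy())
    month_arr = visits["visit_month"].to_numpy()

    values: dict[str, np.ndarray] = {}
    for marker in MARKERS:
        model = spec.markers[marker]
        offs = np.asarray(model.seasonal_offsets)[month_arr - 1]
        v = model.trend_at(t_idx) + offs + rng.normal(0.0, model.noise_sd, size=m)
        values[marker] = np.maximum(np.round(v, 1), 1.0)

    retest = rng.random(m) < _BP_RETEST_RATE
    sbp1 = np.where(retest, np.nan, values["sbp"])
    dbp1 = np.where(retest, np.nan, values["dbp"])
    sbp2 = np.round(values["sbp"] + rng.normal(0.0, 3.0, size=m), 1)
    dbp2 = np.round(values["dbp"] + rng.normal(0.0, 2.0, size=m), 1)

    df = pd.DataFrame(
        {
            "record_id": np.arange(1, m + 1),
            "subject_id": visits["subject_id"].to_numpy(),
            "sex": visits["sex"].to_numpy(),
            "birth_date": visits["birth_date"].to_numpy(),
            "visit_date": pd.to_datetime(
                {
                    "year": visits["visit_year"],
                    "month": visits["visit_month"],
                    "day": visits["visit_day"],
                }
            ),
            "med_diabetes": "no",
            "med_hypertension": "no",
            "med_dyslipidemia": "no",
            "wc_cm": values["wc"],
            "sbp1_mmhg": sbp1,
            "sbp2_mmhg": sbp2,
            "dbp1_mmhg": dbp1,
            "dbp2_mmhg": dbp2,
            "tg_mgdl": values["tg"],
            "hdlc_mgdl": values["hdlc"],
            "fpg_mgdl": values["fpg"],
        }
    )
    manifest = ArtifactManifest()

    # 1. duplicates: an older extra record in the same fiscal year
    fy = _fiscal_year(df["visit_date"].dt.year.to_numpy(), df["visit_date"].dt.month.to_numpy())
    dup_mask = rng.random(m) < spec.dup_rate
    dup_rows = []
    next_id = m + 1
    for i in np.flatnonzero(dup_mask):
        orig_date = df["visit_date"].iloc[i]
        fy_start = pd.Timestamp(year=int(fy[i]), month=4, day=1)
        floor = max(fy_start, start_date)
        back = int(rng.integers(1, 61))
        dup_date = orig_date - pd.Timedelta(days=back)
        if dup_date < floor:
            dup_date = floor
        if dup_date >= orig_date:
            continue
        row = df.iloc[i].copy()
        row["record_id"] = next_id
        row["visit_date"] = dup_date
        dup_rows.append(row)
        manifest.duplicates.append(next_id)
        next_id += 1
    if dup_rows:
        df = pd.concat([df, pd.DataFrame(dup_rows)], ignore_index=True)

    # 2. medication / missing self-report, on subjects with no planted duplicate
    dup_subjects = set(df.loc[df["record_id"].isin(manifest.duplicates), "subject_id"])
    med_pick = rng.random(n) < spec.medicated_rate
    missing_pick = rng.random(n) < _MISSING_REPORT_SHARE
    which_med = rng.integers(0, 3, size=n)
    med_cols = ["med_diabetes", "med_hypertension", "med_dyslipidemia"]
    affected: dict[int, tuple[str, int]] = {}
    for j in range(n):
        sid = int(subject_id[j])
        if not med_pick[j] or sid in dup_subjects:
            continue
        affected[sid] = ("missing" if missing_pick[j] else "yes", int(which_med[j]))
    if affected:
        sid_arr = df["subject_id"].to_numpy()
        for sid, (kind, col_idx) in affected.items():
            idx = np.flatnonzero(sid_arr == sid)
            col = med_cols[col_idx]
            if kind == "yes":
                df.loc[df.index[idx], col] = "yes"
                manifest.medicated_records.extend(df["record_id"].iloc[idx].tolist())
            else:
                df.loc[df.index[idx], col] = np.nan
                manifest.missing_report_records.extend(df["record_id"].iloc[idx].tolist())

    # 3./4. sentinels and gross outliers, on records that survive the
    # earlier filters (so marker-cleaning ground truth stays exact)
    excluded_ids = set(manifest.duplicates) | set(manifest.medicated_records) | set(
        manifest.missing_report_records
    )
    eligible = ~df["record_id"].isin(excluded_ids).to_numpy()
    total = len(df)
    sentinel_cells = rng.random((total, len(MARKERS))) < spec.sentinel_rate
    outlier_cells = rng.random((total, len(MARKERS))) < spec.gross_outlier_rate
    sentinel_cells &= eligible[:, None]
    outlier_cells &= eligible[:, None] & ~sentinel_cells
    sentinel_value = np.where(rng.random((total, len(MARKERS))) < 0.5, 0.0, 9.999)

    for k, marker in enumerate(MARKERS):
        rows_s = np.flatnonzero(sentinel_cells[:, k])
        rows_o = np.flatnonzero(outlier_cells[:, k])
        if marker in ("sbp", "dbp"):
            col1, col2 = (f"{marker}1_mmhg", f"{marker}2_mmhg")
            for i in rows_s:
                df.loc[df.index[i], col1] = sentinel_value[i, k]
                df.loc[df.index[i], col2] = np.nan
                manifest.sentinels.append((int(df["record_id"].iloc[i]), marker))
            for i in rows_o:
                tgt = col1 if not np.isnan(df[col1].iloc[i]) else col2
                df.loc[df.index[i], tgt] = np.round(df[tgt].iloc[i] * 10.0, 1)
                manifest.gross_outliers.append((int(df["record_id"].iloc[i]), marker))
        else:
            col = MARKER_COLUMNS[marker]
            for i in rows_s:
                df.loc[df.index[i], col] = sentinel_value[i, k]
                manifest.sentinels.append((int(df["record_id"].iloc[i]), marker))
            for i in rows_o:
                df.loc[df.index[i], col] = np.round(df[col].iloc[i] * 10.0, 1)
                manifest.gross_outliers.append((int(df["record_id"].iloc[i]), marker))

    df = df.sort_values(["subject_id", "visit_date", "record_id"], kind="stable")
    df = df.reset_index(drop=True)
    return df, manifest


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DATE_COLS = ["birth_date", "visit_date"]


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for c in _DATE_COLS:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=_DATE_COLS)
    for c in ("med_diabetes", "med_hypertension", "med_dyslipidemia"):
        df[c] = df[c].where(df[c].notna(), np.nan)
    return df
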