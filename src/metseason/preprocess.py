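"""Subject-selection and measurement-cleaning filters for checkup tables.

The cleaning pipeline applies, in order:

1. removal of all records of subjects whose sex or birth date is not
   constant across visits,
2. fiscal-year deduplication — when a subject has several records in one
   Japanese fiscal year (April 1 – March 31) only the most recent is kept,
3. exclusion of records whose self-report indicates current medication for
   diabetes, hypertension or dyslipidemia, or whose self-report is absent,
4. blood-pressure resolution (first reading if valid, else the second),
5. per-marker cleaning: sentinel values (literal 0 or 9.999 by default)
   are blanked, then values in the extreme tails of the marker's
   distribution are blanked — by default everything at or beyond the
   0.005th percentile from either end.

Each stage returns a :class:`FilterReport` whose counts balance exactly
(records in = records out + records removed), so the whole selection can
be audited like a subject-flow diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import MARKER_COLUMNS, MARKERS

__all__ = [
    "CleaningConfig",
    "FilterReport",
    "fiscal_year",
    "drop_inconsistent_subjects",
    "dedup_fiscal_year",
    "exclude_medicated",
    "resolve_blood_pressure",
    "trim_marker_outliers",
    "run_preprocess",
]

_MED_COLS = ["med_diabetes", "med_hypertension", "med_dyslipidemia"]


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds for measurement cleaning.

    ``trim_percentile`` is the percentile trimmed from *each* tail, in
    percent: the default 0.005 blanks values at or beyond the 0.005th and
    99.995th percentiles (fraction 5e-5 per tail).  ``sentinels`` is the
    set of literal codes treated as invalid; ``stratify_by_sex`` computes
    the trim quantiles separately per sex.
    """

    sentinels: tuple[float, ...] = (0.0, 9.999)
    trim_percentile: float = 0.005
    stratify_by_sex: bool = False

    @property
    def trim_fraction(self) -> float:
        return self.trim_percentile / 100.0


@dataclass
class FilterReport:
    """Removal accounting for one pipeline stage."""

    stage: str
    n_in: int
    n_out: int
    removed: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_out + self.removed:
            raise ValueError(
                f"{self.stage}: counts do not balance "
                f"({self.n_in} != {self.n_out} + {self.removed})"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def fiscal_year(dates) -> np.ndarray:
    """Japanese fiscal year of each date (April 1 – March 31)."""
    dates = pd.DatetimeIndex(dates)
    return dates.year.to_numpy() - (dates.month.to_numpy() < 4)


def drop_inconsistent_subjects(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Remove every record of subjects with >1 distinct sex or birth date."""
    n_in = len(records)
    if n_in == 0:
        return records, FilterReport("consistency", 0, 0, 0, {"subjects_removed": 0})
    per_subject = records.groupby("subject_id").agg(
        n_sex=("sex", "nunique"), n_birth=("birth_date", "nunique")
    )
    bad = per_subject.index[(per_subject["n_sex"] > 1) | (per_subject["n_birth"] > 1)]
    keep = ~records["subject_id"].isin(bad)
    out = records.loc[keep]
    report = FilterReport(
        "consistency", n_in, len(out), int((~keep).sum()), {"subjects_removed": len(bad)}
    )
    return out, report


def dedup_fiscal_year(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Keep only the latest record per subject and fiscal year.

    Records sharing an exact visit date tie-break by file order: the one
    appearing last in the table wins.
    """
    n_in = len(records)
    if n_in == 0:
        return records, FilterReport("dedup_fiscal_year", 0, 0, 0)
    fy = fiscal_year(records["visit_date"])
    order = np.arange(n_in)
    tmp = records.assign(_fy=fy, _ord=order)
    latest = (
        tmp.sort_values(["visit_date", "_ord"], kind="stable")
        .groupby(["subject_id", "_fy"], sort=False)
        .tail(1)
    )
    keep_idx = latest.index
    out = records.loc[records.index.isin(keep_idx)]
    report = FilterReport("dedup_fiscal_year", n_in, len(out), n_in - len(out))
    return out, report


def exclude_medicated(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop records medicated for any of the three conditions or lacking a report."""
    n_in = len(records)
    if n_in == 0:
        return records, FilterReport("medication", 0, 0, 0)
    med = records[_MED_COLS]
    drop = (med == "yes").any(axis=1) | med.isna().any(axis=1)
    out = records.loc[~drop]
    report = FilterReport(
        "medication",
        n_in,
        len(out),
        int(drop.sum()),
        {
            "medicated": int((med == "yes").any(axis=1).sum()),
            "missing_report": int((med.isna().any(axis=1) & ~(med == "yes").any(axis=1)).sum()),
        },
    )
    return out, report


def _resolve_pair(first, second, sentinels: Iterable[float]) -> np.ndarray:
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    valid1 = ~np.isnan(first)
    valid2 = ~np.isnan(second)
    for s in sentinels:
        valid1 &= first != s
        valid2 &= second != s
    return np.where(valid1, first, np.where(valid2, second, np.nan))


def resolve_blood_pressure(
    records: pd.DataFrame, config: CleaningConfig | None = None
) -> pd.DataFrame:
    """Add resolved ``sbp_mmhg``/``dbp_mmhg`` columns.

    The first measurement is used when valid (present and not a sentinel
    code), otherwise the second; if both are invalid the resolved value is
    missing and the record drops out of blood-pressure analyses only.
    """
    config = config or CleaningConfig()
    out = records.copy()
    out["sbp_mmhg"] = _resolve_pair(
        records["sbp1_mmhg"], records["sbp2_mmhg"], config.sentinels
    )
    out["dbp_mmhg"] = _resolve_pair(
        records["dbp1_mmhg"], records["dbp2_mmhg"], config.sentinels
    )
    return out


def _trim_column(values: np.ndarray, config: CleaningConfig) -> tuple[np.ndarray, dict]:
    """Blank sentinels, then both extreme tails; return mask-applied values."""
    vals = values.astype(float).copy()
    sentinel_mask = np.isin(vals, list(config.sentinels)) & ~np.isnan(vals)
    vals[sentinel_mask] = np.nan
    obs = ~np.isnan(vals)
    n_obs = int(obs.sum())
    frac = config.trim_fraction
    info = {"sentinels": int(sentinel_mask.sum()), "trimmed": 0, "trim_applied": False}
    if frac > 0 and n_obs >= 1.0 / frac:
        lo = np.quantile(vals[obs], frac)
        hi = np.quantile(vals[obs], 1.0 - frac)
        tail = obs & ((vals <= lo) | (vals >= hi))
        vals[tail] = np.nan
        info.update(trimmed=int(tail.sum()), trim_applied=True, lo=float(lo), hi=float(hi))
    return vals, info


def trim_marker_outliers(
    records: pd.DataFrame, marker: str, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Blank sentinel and extreme-tail values of one marker column.

    Only the marker cells are set missing; records remain for the other
    markers.  If the column holds fewer values than one over the trim
    fraction, the percentile trim is skipped (the quantiles would be
    determined by single observations) and only sentinels are blanked.
    """
    config = config or CleaningConfig()
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    col = MARKER_COLUMNS[marker]
    out = records.copy()
    details: dict = {}
    if config.stratify_by_sex:
        for sex in ("male", "female"):
            mask = (records["sex"] == sex).to_numpy()
            trimmed, info = _trim_column(records.loc[mask, col].to_numpy(), config)
            out.loc[mask, col] = trimmed
            details[sex] = info
        removed = sum(d["sentinels"] + d["trimmed"] for d in details.values())
    else:
        trimmed, info = _trim_column(records[col].to_numpy(), config)
        out[col] = trimmed
        details = info
        removed = info["sentinels"] + info["trimmed"]
    # cell-level accounting: records are retained, values blanked
    report = FilterReport(f"trim[{marker}]", len(records), len(records), 0, details | {"values_blanked": removed})
    return out, report


def run_preprocess(
    records: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, list[FilterReport]]:
    """Apply the full selection and cleaning pipeline in order."""
    config = config or CleaningConfig()
    reports: list[FilterReport] = []
    out, rep = drop_inconsistent_subjects(records)
    reports.append(rep)
    out, rep = dedup_fiscal_year(out)
    reports.append(rep)
    out, rep = exclude_medicated(out)
    reports.append(rep)
    out = resolve_blood_pressure(out, config)
    for marker in MARKERS:
        out, rep = trim_marker_outliers(out, marker, config)
        reports.append(rep)
    return out, reports
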