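"""Monthly aggregation and seasonal summaries of cleaned checkup records.

Builds the monthly series the decomposition consumes (marker means and
prevalence of out-of-range or syndrome-positive records), summarises a
decomposition's seasonal component per calendar month across years, and
computes the peak-versus-trough statistics: the two calendar months with
the highest and lowest across-year mean seasonal value are fixed, and the
difference between them is taken within each year, reported as mean ± SD
over years.

Strata follow the conventional epidemiological split: sex crossed with
age at the visit (<65 = middle-aged, >=65 = elderly).  Season membership
is spring = March–May, summer = June–August, autumn = September–November,
winter = December–February.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .cohort import MARKER_COLUMNS, MARKERS
from .stl import Decomposition, MonthlySeries
from .mets import MET, NOT_MET

__all__ = [
    "SeasonalSummary",
    "StratumKey",
    "monthly_prevalence",
    "monthly_mean",
    "summarize_seasonal",
    "season_descriptives",
    "stratify",
    "age_at_visit",
    "season_of_month",
]

_SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def season_of_month(month) -> np.ndarray:
    """Map calendar month 1..12 to its season name."""
    return np.vectorize(_SEASONS.__getitem__)(np.asarray(month))


@dataclass(frozen=True)
class SeasonalSummary:
    """Per-calendar-month summary of a seasonal component across years.

    ``month_mean``/``month_sd``/``month_count`` are indexed by calendar
    month 1..12.  ``peak_month`` and ``trough_month`` are the months with
    the highest and lowest across-year mean; ``year_diffs`` holds, for
    each calendar year observing both months, the within-year difference
    seasonal(peak) - seasonal(trough), with ``diff_mean``/``diff_sd`` its
    mean and sample standard deviation.
    """

    month_mean: np.ndarray
    month_sd: np.ndarray
    month_count: np.ndarray
    peak_month: int
    trough_month: int
    year_diffs: dict[int, float]
    diff_mean: float
    diff_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": np.arange(1, 13),
                "seasonal_mean": self.month_mean,
                "seasonal_sd": self.month_sd,
                "n_years": self.month_count,
            }
        )


class StratumKey(NamedTuple):
    sex: str
    age_band: str  # "middle" (<65) or "elderly" (>=65)


def _monthly_groupby(records: pd.DataFrame) -> pd.PeriodIndex:
    return pd.PeriodIndex(pd.DatetimeIndex(records["visit_date"]), freq="M")


def _to_monthly_series(
    s: pd.Series, window: tuple[tuple[int, int], tuple[int, int]] | None
) -> MonthlySeries:
    if window is not None:
        start = pd.Period(year=window[0][0], month=window[0][1], freq="M")
        end = pd.Period(year=window[1][0], month=window[1][1], freq="M")
        s = s.reindex(pd.period_range(start, end, freq="M"))
    return MonthlySeries.from_series(s)


def monthly_prevalence(
    records: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], np.ndarray],
    window: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> MonthlySeries:
    """Percent of determinate records the predicate labels positive, per month.

    ``predicate`` maps the record table to per-record outcomes: either
    tri-state labels (``mets``/``not_mets``/``indeterminate``) or numeric
    flags coded 1/0/NaN.  Indeterminate records leave the denominator;
    months with no determinate records are missing.
    """
    outcome = np.asarray(predicate(records))
    if outcome.dtype.kind in "OUS":
        pos = outcome == MET
        neg = outcome == NOT_MET
    else:
        out = outcome.astype(float)
        pos = out == 1.0
        neg = out == 0.0
    per = _monthly_groupby(records)
    tab = pd.DataFrame({"pos": pos, "neg": neg}, index=per).groupby(level=0).sum()
    denom = tab["pos"] + tab["neg"]
    prev = 100.0 * tab["pos"] / denom.where(denom > 0)
    return _to_monthly_series(prev, window)


def monthly_mean(
    records: pd.DataFrame,
    marker: str,
    window: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> MonthlySeries:
    """Arithmetic mean of the non-missing marker values per year-month."""
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    vals = records[MARKER_COLUMNS[marker]].astype(float)
    per = _monthly_groupby(records)
    means = vals.groupby(per).mean()
    return _to_monthly_series(means, window)


def summarize_seasonal(decomp: Decomposition) -> SeasonalSummary:
    """Across-year per-month summary and peak-trough statistics of S_t.

    The peak and trough are the calendar months with the highest and
    lowest across-year mean; the per-year differences are then taken
    between those two fixed months in every calendar year that observes
    both.  SDs use the n-1 denominator and are NaN when fewer than two
    years contribute.
    """
    months = decomp.series.calendar_months
    years = decomp.series.years
    s = decomp.seasonal
    mean = np.full(12, np.nan)
    sd = np.full(12, np.nan)
    count = np.zeros(12, dtype=int)
    for m in range(1, 13):
        vals = s[(months == m) & ~np.isnan(s)]
        count[m - 1] = vals.size
        if vals.size:
            mean[m - 1] = vals.mean()
        if vals.size >= 2:
            sd[m - 1] = vals.std(ddof=1)
    peak = int(np.nanargmax(mean)) + 1
    trough = int(np.nanargmin(mean)) + 1
    year_diffs: dict[int, float] = {}
    for yr in np.unique(years):
        at = lambda m: s[(years == yr) & (months == m)]
        hi, lo = at(peak), at(trough)
        if hi.size == 1 and lo.size == 1 and not (np.isnan(hi[0]) or np.isnan(lo[0])):
            year_diffs[int(yr)] = float(hi[0] - lo[0])
    diffs = np.array(list(year_diffs.values()))
    diff_mean = float(diffs.mean()) if diffs.size else float("nan")
    diff_sd = float(diffs.std(ddof=1)) if diffs.size >= 2 else float("nan")
    return SeasonalSummary(
        month_mean=mean,
        month_sd=sd,
        month_count=count,
        peak_month=peak,
        trough_month=trough,
        year_diffs=year_diffs,
        diff_mean=diff_mean,
        diff_sd=diff_sd,
    )


def season_descriptives(
    records: pd.DataFrame, markers: tuple[str, ...] = MARKERS
) -> pd.DataFrame:
    """Median and IQR of each marker per sex and season, plus age.

    Returns a tidy frame with one row per (sex, season, variable) holding
    the median, 25th and 75th percentiles and the count of non-missing
    values.
    """
    work = records.copy()
    work["season"] = season_of_month(pd.DatetimeIndex(work["visit_date"]).month)
    work["age_years"] = age_at_visit(work)
    variables = {"age_years": "age_years"} | {m: MARKER_COLUMNS[m] for m in markers}
    rows = []
    for (sex, season), grp in work.groupby(["sex", "season"], sort=True):
        for name, col in variables.items():
            vals = grp[col].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "sex": sex,
                    "season": season,
                    "variable": name,
                    "n": vals.size,
                    "median": np.median(vals) if vals.size else np.nan,
                    "q1": np.percentile(vals, 25) if vals.size else np.nan,
                    "q3": np.percentile(vals, 75) if vals.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def age_at_visit(records: pd.DataFrame) -> np.ndarray:
    """Completed years of age on the visit date."""
    birth = pd.DatetimeIndex(records["birth_date"])
    visit = pd.DatetimeIndex(records["visit_date"])
    if (visit < birth).any():
        raise ValueError("visit_date precedes birth_date for some records")
    before_birthday = (visit.month < birth.month) | (
        (visit.month == birth.month) & (visit.day < birth.day)
    )
    return (visit.year - birth.year - before_birthday).to_numpy()


def stratify(records: pd.DataFrame, age_cut: int = 65) -> dict[StratumKey, pd.DataFrame]:
    """Partition records by sex and age band (<age_cut vs >=age_cut at visit)."""
    age = age_at_visit(records)
    bands = np.where(age >= age_cut, "elderly", "middle")
    out: dict[StratumKey, pd.DataFrame] = {}
    for sex in ("male", "female"):
        for band in ("middle", "elderly"):
            mask = (records["sex"].to_numpy() == sex) & (bands == band)
            out[StratumKey(sex, band)] = records.loc[mask]
    return out
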