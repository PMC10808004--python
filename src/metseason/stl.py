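"""Robust seasonal-trend decomposition of monthly series using LOESS (STL).

An observed monthly series :math:`Y_t` is split additively into a secular
trend :math:`T_t`, a 12-month seasonal component :math:`S_t` constrained to
average zero, and a residual :math:`R_t`:

.. math:: Y_t = T_t + S_t + R_t

The decomposition alternates two nested loops.  The *inner* loop smooths
each cycle-subseries (all Januaries, all Februaries, ...) with locally
weighted linear regression (LOESS), removes the low-frequency content of
the interleaved result with a triple moving average plus LOESS, and then
re-estimates the trend from the deseasonalised series.  The *outer* loop
recomputes bisquare robustness weights from the residuals so that gross
outliers are progressively down-weighted.

LOESS here uses the tricube distance kernel over a nearest-neighbour
window; robustness weights, when supplied, multiply the tricube weights.
Missing observations are simply skipped in every local fit, so series with
gaps decompose without imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "StlConfig",
    "Decomposition",
    "RobustnessWeights",
    "tricube_weight",
    "bisquare_weight",
    "loess",
    "cycle_subseries_smooth",
    "low_pass_filter",
    "stl_decompose",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonthlySeries:
    """A value per calendar month over a contiguous window.

    Parameters
    ----------
    start
        ``(year, month)`` of the first value, month in 1..12.
    values
        One value per month; ``NaN`` marks a missing month.
    """

    start: tuple[int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        y, m = self.start
        if not 1 <= m <= 12:
            raise ValueError(f"start month must be in 1..12, got {m}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(
            start=pd.Period(year=self.start[0], month=self.start[1], freq="M"),
            periods=len(self),
            freq="M",
        )

    @property
    def calendar_months(self) -> np.ndarray:
        """Calendar month (1..12) of each element."""
        m0 = self.start[1] - 1
        return (m0 + np.arange(len(self))) % 12 + 1

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.periods.year)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.periods)

    @classmethod
    def from_series(cls, s: pd.Series) -> "MonthlySeries":
        """Build from a pandas Series indexed by a monthly PeriodIndex."""
        idx = pd.PeriodIndex(s.index, freq="M")
        if len(idx) == 0:
            raise ValueError("empty series")
        full = pd.period_range(idx[0], idx[-1], freq="M")
        s = s.reindex(full)
        return cls(start=(full[0].year, full[0].month), values=s.to_numpy(float))


def _require_odd_span(name: str, value: int) -> None:
    if value < 3 or value % 2 == 0:
        raise ValueError(f"{name} must be odd and >= 3, got {value}")


@dataclass(frozen=True)
class StlConfig:
    """Smoothing parameters for the decomposition.

    Defaults follow the classical recommendations for monthly data:
    seasonal span 7, trend span the smallest odd integer not less than
    ``1.5 * period / (1 - 1.5 / seasonal_span)`` (23 for monthly data) and
    low-pass span the smallest odd integer >= the period (13).  Two inner
    iterations and five robustness (outer) iterations, locally linear fits
    throughout.
    """

    period: int = 12
    seasonal_span: int = 7
    trend_span: int = 23
    lowpass_span: int = 13
    inner_iterations: int = 2
    outer_iterations: int = 5
    degree: int = 1

    def __post_init__(self) -> None:
        if self.period < 2:
            raise ValueError(f"period must be >= 2, got {self.period}")
        _require_odd_span("seasonal_span", self.seasonal_span)
        _require_odd_span("trend_span", self.trend_span)
        _require_odd_span("lowpass_span", self.lowpass_span)
        if self.inner_iterations < 1:
            raise ValueError("inner_iterations must be >= 1")
        if self.outer_iterations < 0:
            raise ValueError("outer_iterations must be >= 0")
        if self.degree not in (0, 1):
            raise ValueError(f"degree must be 0 or 1, got {self.degree}")


@dataclass(frozen=True)
class RobustnessWeights:
    """Per-point bisquare weights in [0, 1] with the residual scale used."""

    weights: np.ndarray
    r_med: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any((w < 0) | (w > 1)):
            raise ValueError("robustness weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class Decomposition:
    """Aligned trend/seasonal/residual components of a monthly series."""

    series: MonthlySeries
    trend: np.ndarray
    seasonal: np.ndarray
    resid: np.ndarray
    weights: RobustnessWeights | None = None

    @property
    def observed(self) -> np.ndarray:
        return self.series.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year_month": self.series.periods.astype(str),
                "observed": self.observed,
                "trend": self.trend,
                "seasonal": self.seasonal,
                "resid": self.resid,
            }
        )


# ---------------------------------------------------------------------------
# weight kernels
# ---------------------------------------------------------------------------


def tricube_weight(distance, d_cq: float):
    """Tricube neighbourhood weight ``(1 - (d/d_cq)^3)^3`` for d/d_cq < 1.

    ``d_cq`` is the distance from the fit point to the farthest of its q
    nearest neighbours; points at or beyond it get weight zero.
    """
    if d_cq <= 0:
        raise ValueError(f"d_cq must be positive, got {d_cq}")
    u = np.abs(np.asarray(distance, dtype=float)) / d_cq
    w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)
    return w if w.ndim else float(w)


def bisquare_weight(residual, r_med: float):
    """Bisquare robustness weight ``(1 - (|r|/(6 r_med))^2)^2``.

    Residuals of magnitude at least ``6 * r_med`` (six times the median
    absolute residual) receive weight zero.  When ``r_med`` is zero the
    residuals carry no scale information and every point gets weight one.
    """
    r = np.abs(np.asarray(residual, dtype=float))
    if r_med <= 0:
        w = np.ones_like(r)
        return w if w.ndim else float(w)
    u = r / (6.0 * r_med)
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------


def _as_weight_array(robustness, n: int) -> np.ndarray:
    if robustness is None:
        return np.ones(n)
    if isinstance(robustness, RobustnessWeights):
        return np.asarray(robustness.weights, dtype=float)
    return np.asarray(robustness, dtype=float)


def _wls_value(xs: np.ndarray, ys: np.ndarray, w: np.ndarray, degree: int, xc: float) -> float:
    """Weighted least-squares fit evaluated at xc (x centred for stability).

    A sloped fit needs at least three supported points; thinner windows
    fall back to the weighted mean so that two surviving points cannot
    launch an arbitrarily wild extrapolation.
    """
    m = w > 0
    xw, yw, ww = xs[m], ys[m], w[m]
    if degree == 0 or xw.size < 3 or np.ptp(xw) == 0.0:
        return float(np.sum(ww * yw) / np.sum(ww))
    sw = np.sqrt(ww)
    design = np.column_stack([np.ones_like(xw), xw - xc]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(design, yw * sw, rcond=None)
    return float(beta[0])


def loess(
    x: Sequence[float],
    y: Sequence[float],
    q: int,
    degree: int = 1,
    robustness=None,
    eval_at: Sequence[float] | None = None,
) -> np.ndarray:
    """Locally weighted polynomial regression with a q-nearest window.

    At each evaluation point the q nearest observed points (ties kept in
    full) enter a weighted least-squares fit of the given degree, weighted
    by the tricube kernel of distance over ``d_cq`` — the distance to the
    farthest of those q neighbours — times the optional robustness weight.
    When q exceeds the number of observed points, ``d_cq`` is inflated by
    ``q / n`` as in the original STL formulation.  Missing ``y`` values are
    skipped.

    Returns the fitted values at ``eval_at`` (default: at ``x``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    rho = _as_weight_array(robustness, y.size)
    keep = ~np.isnan(y)
    xs, ys, rs = x[keep], y[keep], rho[keep]
    n = xs.size
    if n == 0:
        raise ValueError("no observed points to fit")
    pts = x if eval_at is None else np.asarray(eval_at, dtype=float)
    q_eff = min(q, n)
    out = np.empty(pts.size)
    for j, xc in enumerate(pts):
        d = np.abs(xs - xc)
        d_cq = float(np.partition(d, q_eff - 1)[q_eff - 1])
        if q > n:
            d_cq *= q / n
        if d_cq <= 0.0:
            # every neighbour coincides with the fit point
            base = np.where(d == 0.0, 1.0, 0.0)
        else:
            base = tricube_weight(d, d_cq)
        w = base * rs
        if not np.any(w > 0):
            # every neighbour is flagged as an outlier: the robustness
            # weights carry no information in this window, so fall back
            # to the distance weights alone rather than fail the fit
            w = base
        if not np.any(w > 0):
            raise ValueError(f"all LOESS weights vanish at evaluation point {xc}")
        out[j] = _wls_value(xs, ys, w, degree, xc)
    return out


# ---------------------------------------------------------------------------
# STL building blocks
# ---------------------------------------------------------------------------


def _series_values(series) -> np.ndarray:
    if isinstance(series, MonthlySeries):
        return series.values
    return np.asarray(series, dtype=float)


def cycle_subseries_smooth(detrended, config: StlConfig, robustness=None) -> np.ndarray:
    """Smooth each cycle-subseries and re-interleave, extended by one period.

    A cycle-subseries collects the values sharing a position in the cycle
    (e.g. every April across years).  Each is LOESS-smoothed over year
    index with span ``seasonal_span`` and evaluated at every member plus
    one extrapolated position before the first and after the last year, so
    the interleaved output has length ``n + 2 * period`` — the margin the
    low-pass filter consumes.
    """
    vals = _series_values(detrended)
    n = vals.size
    n_p = config.period
    rho = _as_weight_array(robustness, n)
    out = np.empty(n + 2 * n_p)
    for p in range(n_p):
        idx = np.arange(p, n, n_p)
        sub = vals[idx]
        if np.all(np.isnan(sub)):
            raise ValueError(f"cycle-subseries {p} has no observed values")
        k = idx.size
        fitted = loess(
            np.arange(k, dtype=float),
            sub,
            q=config.seasonal_span,
            degree=config.degree,
            robustness=rho[idx],
            eval_at=np.arange(-1, k + 1, dtype=float),
        )
        out[p::n_p][: k + 2] = fitted
    return out


def _moving_average(a: np.ndarray, width: int) -> np.ndarray:
    return np.convolve(a, np.full(width, 1.0 / width), mode="valid")


def low_pass_filter(extended: np.ndarray, config: StlConfig) -> np.ndarray:
    """Extract the low-frequency content of an extended seasonal candidate.

    Applies moving averages of length ``period``, ``period`` and 3 in turn
    (dropping the ``2 * period`` margin) and finishes with a LOESS smooth of
    span ``lowpass_span``.  A full-period moving average annihilates any
    zero-sum 12-month pattern, so what remains is the trend leakage that
    must be subtracted from the seasonal candidate.
    """
    extended = np.asarray(extended, dtype=float)
    n_p = config.period
    n = extended.size - 2 * n_p
    if n < 1:
        raise ValueError(
            f"input length {extended.size} too short for period {n_p}"
        )
    smoothed = _moving_average(extended, n_p)
    smoothed = _moving_average(smoothed, n_p)
    smoothed = _moving_average(smoothed, 3)
    if smoothed.size != n:
        raise AssertionError("moving-average cascade returned wrong length")
    t = np.arange(n, dtype=float)
    return loess(t, smoothed, q=config.lowpass_span, degree=1, eval_at=t)


def _pilot_weights(y: np.ndarray, period: int) -> np.ndarray:
    """Initial robustness weights from a moving-median residual screen.

    Before any smoothing has run there are no model residuals, yet a
    first pass fitted with unit weights lets a gross outlier contaminate
    its whole cycle-subseries, and the bisquare reweighting can then lock
    innocent points out permanently.  A centred running median over one
    period is insensitive to such outliers, so the deviations from it
    give a serviceable first residual scale: points that are extreme on
    that scale start the first inner pass already down-weighted.
    """
    n = y.size
    half = period // 2
    med = np.empty(n)
    for i in range(n):
        window = y[max(0, i - half) : min(n, i + half + 1)]
        window = window[~np.isnan(window)]
        med[i] = np.median(window) if window.size else np.nan
    resid = y - med
    r_med = float(np.nanmedian(np.abs(resid)))
    w = bisquare_weight(np.nan_to_num(resid), r_med)
    return np.where(np.isnan(resid), 1.0, w)


def stl_decompose(series: MonthlySeries, config: StlConfig | None = None) -> Decomposition:
    """Decompose a monthly series into trend, seasonal and residual.

    Runs the inner smoothing loop ``inner_iterations`` times, then
    ``outer_iterations`` further rounds, each recomputing bisquare
    weights from the current residuals before re-running the inner loop.
    When the outer loop is active the very first pass already uses pilot
    weights from a moving-median screen (see :func:`_pilot_weights`);
    with ``outer_iterations = 0`` the decomposition is non-robust and
    all weights are one.  The seasonal component is re-centred to zero
    mean, the offset moved into the trend, and the residual defined as
    ``Y - T - S`` so additivity is exact at every observed month.
    """
    config = config or StlConfig()
    y = np.asarray(series.values, dtype=float)
    n = y.size
    if n < 2 * config.period:
        raise ValueError(
            f"series length {n} shorter than two periods ({2 * config.period})"
        )
    observed = ~np.isnan(y)
    if not observed.any():
        raise ValueError("series has no observed values")

    t_grid = np.arange(n, dtype=float)
    trend = np.zeros(n)
    seasonal = np.zeros(n)
    rho: np.ndarray | None = None
    if config.outer_iterations > 0:
        rho = _pilot_weights(y, config.period)
    r_med = float("nan")

    for outer in range(config.outer_iterations + 1):
        for _ in range(config.inner_iterations):
            detrended = y - trend
            cands = cycle_subseries_smooth(detrended, config, robustness=rho)
            lowpass = low_pass_filter(cands, config)
            seasonal = cands[config.period : config.period + n] - lowpass
            deseason = y - seasonal
            trend = loess(
                t_grid,
                deseason,
                q=config.trend_span,
                degree=config.degree,
                robustness=rho,
                eval_at=t_grid,
            )
        if outer < config.outer_iterations:
            resid = y - trend - seasonal
            r_med = float(np.nanmedian(np.abs(resid)))
            w = bisquare_weight(np.nan_to_num(resid), r_med)
            rho = np.where(observed, w, 1.0)

    offset = float(np.mean(seasonal))
    seasonal = seasonal - offset
    trend = trend + offset
    resid = y - trend - seasonal
    if np.isnan(trend).any() or np.isnan(seasonal).any():
        raise ValueError("decomposition produced NaN components")
    weights = RobustnessWeights(weights=rho, r_med=r_med) if rho is not None else None
    return Decomposition(
        series=series, trend=trend, seasonal=seasonal, resid=resid, weights=weights
    )
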