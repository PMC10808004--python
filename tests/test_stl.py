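"""Unit and property tests for LOESS and the seasonal-trend decomposition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metseason import MonthlySeries, StlConfig, stl_decompose
from metseason.stl import (
    bisquare_weight,
    cycle_subseries_smooth,
    loess,
    low_pass_filter,
    tricube_weight,
)

from conftest import make_benchmark_series


def loess_oracle(x, y, q, degree, rho=None, eval_at=None):
    """Brute-force LOESS via explicit weighted normal equations.

    Independent of the implementation under test: neighbourhood distance,
    tricube weights and the 2x2 normal-equation solve are all written out
    directly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho = np.ones_like(y) if rho is None else np.asarray(rho, float)
    pts = x if eval_at is None else np.asarray(eval_at, float)
    out = []
    for xc in pts:
        d = np.sort(np.abs(x - xc))
        if q <= len(x):
            d_cq = d[q - 1]
        else:
            d_cq = d[-1] * q / len(x)
        u = np.abs(x - xc) / d_cq
        w = np.where(u < 1, (1 - u**3) ** 3, 0.0) * rho
        if degree == 0 or int(np.sum(w > 0)) < 3:
            # thin windows use the weighted mean (shared fit contract)
            out.append(np.sum(w * y) / np.sum(w))
        else:
            sw, swx = w.sum(), (w * x).sum()
            swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
            det = sw * swxx - swx**2
            b1 = (sw * swxy - swx * swy) / det
            b0 = (swy - b1 * swx) / sw
            out.append(b0 + b1 * xc)
    return np.array(out)


class TestWeightKernels:
    def test_tricube_values(self):
        assert tricube_weight(0.0, 1.0) == 1.0
        assert tricube_weight(1.0, 1.0) == 0.0
        assert tricube_weight(2.0, 1.0) == 0.0
        # (1 - 0.5^3)^3 = 0.875^3
        assert tricube_weight(0.5, 1.0) == pytest.approx(0.669921875, abs=1e-12)

    def test_tricube_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            tricube_weight(0.5, 0.0)

    def test_bisquare_values(self):
        assert bisquare_weight(0.0, 1.0) == 1.0
        assert bisquare_weight(6.0, 1.0) == 0.0
        # |r| = r_med: (1 - (1/6)^2)^2
        assert bisquare_weight(1.0, 1.0) == pytest.approx((1 - 1 / 36) ** 2, abs=1e-12)

    def test_bisquare_zero_scale_gives_unit_weights(self):
        assert bisquare_weight(5.0, 0.0) == 1.0
        np.testing.assert_array_equal(bisquare_weight(np.array([0.0, 3.0]), 0.0), 1.0)


class TestLoess:
    def test_reproduces_affine_data_exactly(self):
        x = np.arange(12.0)
        y = 3.0 - 0.7 * x
        fitted = loess(x, y, q=5, degree=1)
        np.testing.assert_allclose(fitted, y, atol=1e-12)

    def test_constant_data_any_degree(self):
        x = np.arange(9.0)
        for degree in (0, 1):
            np.testing.assert_allclose(
                loess(x, np.full(9, 4.2), q=5, degree=degree), 4.2, atol=1e-12
            )

    @pytest.mark.parametrize("degree", [0, 1])
    @pytest.mark.parametrize("q", [5, 7, 20])
    def test_matches_normal_equations_oracle(self, degree, q):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(7, 16))
            x = np.sort(rng.choice(np.arange(40.0), size=n, replace=False))
            y = rng.normal(0, 5, n)
            rho = rng.uniform(0.2, 1.0, n)
            got = loess(x, y, q=q, degree=degree, robustness=rho)
            want = loess_oracle(x, y, q=q, degree=degree, rho=rho)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_skips_missing_values(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0
        y[4] = np.nan
        fitted = loess(x, y, q=5, degree=1)
        np.testing.assert_allclose(fitted, 2.0 * x + 1.0, atol=1e-10)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            loess(np.arange(3.0), np.full(3, np.nan), q=3)


class TestCycleSubseries:
    CFG = StlConfig()

    def test_periodic_input_repeats_pattern(self):
        pattern = np.arange(12.0) - 5.5
        vals = np.tile(pattern, 5)
        out = cycle_subseries_smooth(vals, self.CFG)
        assert out.size == vals.size + 24
        np.testing.assert_allclose(out, np.tile(pattern, 7), atol=1e-9)

    def test_linear_subseries_extends_line(self):
        # value at month m, year j is m + 2*j: each subseries is affine in j
        n = 72
        months = np.arange(n) % 12
        years = np.arange(n) // 12
        vals = months + 2.0 * years
        out = cycle_subseries_smooth(vals, self.CFG)
        ext_years = np.concatenate([[-1], np.arange(6), [6]])
        for p in range(12):
            np.testing.assert_allclose(out[p::12], p + 2.0 * ext_years, atol=1e-9)

    def test_april_start_window_has_six_member_april_subseries(self):
        # 69 months from April 2012: the April subseries is 2012..2017
        series = MonthlySeries((2012, 4), np.zeros(69))
        assert int(np.sum(series.calendar_months == 4)) == 6
        assert int(np.sum(series.calendar_months == 1)) == 5

    def test_fully_missing_subseries_raises(self):
        vals = np.zeros(48)
        vals[0::12] = np.nan
        with pytest.raises(ValueError):
            cycle_subseries_smooth(vals, self.CFG)


class TestLowPass:
    CFG = StlConfig()

    def test_constant_passes_through(self):
        out = low_pass_filter(np.full(69 + 24, 3.3), self.CFG)
        assert out.size == 69
        np.testing.assert_allclose(out, 3.3, atol=1e-12)

    def test_annihilates_full_period_sinusoid(self):
        t = np.arange(69 + 24)
        wave = np.sin(2 * np.pi * t / 12.0)
        out = low_pass_filter(wave, self.CFG)
        assert np.abs(out[10:-10]).max() < 1e-6

    def test_preserves_affine_interior(self):
        t = np.arange(69 + 24, dtype=float)
        out = low_pass_filter(0.5 * t + 2.0, self.CFG)
        # the centred MA cascade maps extended position k back to original
        # position k, i.e. extended index k + 12
        interior = 0.5 * (np.arange(69) + 12) + 2.0
        np.testing.assert_allclose(out[5:-5], interior[5:-5], atol=1e-8)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            low_pass_filter(np.zeros(10), self.CFG)


class TestStlDecompose:
    def test_constant_series_gives_flat_components(self):
        series = MonthlySeries((2012, 4), np.full(69, 7.0))
        d = stl_decompose(series)
        assert np.abs(d.seasonal).max() < 1e-8
        assert np.abs(d.resid).max() < 1e-8
        np.testing.assert_allclose(d.trend, 7.0, atol=1e-8)

    def test_noiseless_affine_plus_offsets_recovered(self):
        series, offsets = make_benchmark_series(seed=3, noise_sd=0.0)
        d = stl_decompose(series)
        months = series.calendar_months
        recovered = np.array([d.seasonal[months == m].mean() for m in range(1, 13)])
        assert np.abs(recovered - offsets).max() < 0.02 * np.abs(offsets).max()

    def test_additivity_and_centering(self):
        series, _ = make_benchmark_series(seed=5, noise_sd=0.4)
        d = stl_decompose(series)
        scale = np.abs(series.values).max()
        assert np.abs(d.observed - d.trend - d.seasonal - d.resid).max() < 1e-9 * scale
        assert abs(d.seasonal.mean()) < 1e-9 * scale

    def test_missing_values_supported(self):
        series, _ = make_benchmark_series(seed=9, noise_sd=0.3)
        vals = series.values.copy()
        vals[[7, 20, 33]] = np.nan
        d = stl_decompose(MonthlySeries(series.start, vals))
        assert not np.isnan(d.trend).any()
        assert not np.isnan(d.seasonal).any()
        assert np.isnan(d.resid[[7, 20, 33]]).all()
        obs = ~np.isnan(vals)
        np.testing.assert_allclose(
            (d.trend + d.seasonal + d.resid)[obs], vals[obs], atol=1e-9
        )

    def test_single_outlier_barely_moves_seasonal(self):
        series, _ = make_benchmark_series(seed=7, noise_sd=0.2)
        dirty = series.values.copy()
        dirty[30] *= 10.0
        d_clean = stl_decompose(series)
        d_dirty = stl_decompose(MonthlySeries(series.start, dirty))
        amp = d_clean.seasonal.max() - d_clean.seasonal.min()
        assert np.abs(d_clean.seasonal - d_dirty.seasonal).max() < 0.1 * amp

    def test_stability_when_residual_removed(self):
        series, _ = make_benchmark_series(seed=13, noise_sd=0.3)
        d = stl_decompose(series)
        redo = stl_decompose(MonthlySeries(series.start, d.trend + d.seasonal))
        amp = d.seasonal.max() - d.seasonal.min()
        assert np.abs(redo.seasonal - d.seasonal).max() < 0.05 * amp
        assert np.abs(redo.trend - d.trend).max() < 0.05 * amp

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            stl_decompose(MonthlySeries((2012, 1), np.zeros(20)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        noise=st.floats(0.05, 2.0),
        n=st.integers(24, 90),
    )
    def test_additivity_invariant_on_random_series(self, seed, noise, n):
        """Y = T + S + R and mean(S) = 0 hold for arbitrary inputs."""
        series, _ = make_benchmark_series(seed=seed, noise_sd=noise, n=n)
        d = stl_decompose(series)
        scale = max(np.abs(series.values).max(), 1.0)
        assert np.abs(d.observed - d.trend - d.seasonal - d.resid).max() < 1e-9 * scale
        assert abs(d.seasonal.mean()) < 1e-9 * scale


def test_reference_stl_agreement():
    """Per-month seasonal means match statsmodels' robust STL within 5% of amplitude."""
    from statsmodels.tsa.seasonal import STL as ReferenceSTL

    series, _ = make_benchmark_series(seed=21, noise_sd=0.3)
    ours = stl_decompose(series)
    ref = ReferenceSTL(series.values, period=12, seasonal=7, robust=True).fit()
    months = series.calendar_months
    ours_means = np.array([ours.seasonal[months == m].mean() for m in range(1, 13)])
    ref_means = np.array([ref.seasonal[months == m].mean() for m in range(1, 13)])
    amp = ref_means.max() - ref_means.min()
    assert np.abs(ours_means - ref_means).max() < 0.05 * amp
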