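"""Shared fixtures: small synthetic cohorts and benchmark monthly series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metseason import MonthlySeries, SeasonalModelSpec, generate_cohort
from metseason.cohort import MarkerModel, _default_markers


def make_benchmark_series(
    seed: int, noise_sd: float = 0.3, n: int = 69, offset_sd: float = 2.0,
    trend_slope: float = 0.05, start=(2012, 4),
) -> tuple[MonthlySeries, np.ndarray]:
    """Monthly series with known zero-sum offsets; returns (series, offsets).

    Offsets are indexed by calendar month 1..12.
    """
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, offset_sd, 12)
    offsets -= offsets.mean()
    month_idx = (start[1] - 1 + np.arange(n)) % 12  # 0-based calendar month
    y = 10.0 + trend_slope * np.arange(n) + offsets[month_idx]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    return MonthlySeries(start, y), offsets


def quiet_markers(noise_scale: float = 1.0) -> dict[str, MarkerModel]:
    """Default marker models with noise SDs scaled down for small cohorts."""
    out = {}
    for name, m in _default_markers().items():
        out[name] = MarkerModel(
            m.intercept, m.slope, m.seasonal_offsets, m.noise_sd * noise_scale
        )
    return out


@pytest.fixture(scope="session")
def small_spec() -> SeasonalModelSpec:
    return SeasonalModelSpec(n_subjects=600, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def clean_spec() -> SeasonalModelSpec:
    """Artifact-free spec: the preprocessing pipeline should be the identity."""
    return SeasonalModelSpec(
        n_subjects=400,
        seed=11,
        dup_rate=0.0,
        medicated_rate=0.0,
        sentinel_rate=0.0,
        gross_outlier_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_spec):
    return generate_cohort(clean_spec)
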