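"""End-to-end orchestration: cohort -> cleaning -> classification -> STL.

One :func:`run_pipeline` call ingests a record table (from CSV or the
synthetic generator), applies the selection and cleaning filters, labels
every record under both diagnostic criteria, builds per-sex monthly
series (syndrome prevalence, per-marker out-of-range prevalence, marker
means), decomposes each with robust STL and writes tidy CSV outputs plus
optional figures.  All randomness flows from the single config seed, so
identical configs produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    MARKERS,
    SeasonalModelSpec,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .mets import AsianThresholds, JccmsThresholds, classification_table, classify_asian, classify_jccms, flag_markers
from .preprocess import CleaningConfig, run_preprocess
from .seasonal import (
    monthly_mean,
    monthly_prevalence,
    season_descriptives,
    stratify,
    summarize_seasonal,
)
from .stl import Decomposition, StlConfig, stl_decompose

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("metseason")


@dataclass(frozen=True)
class PipelineConfig:
    """Reproducible configuration for a full analysis run."""

    outdir: str | Path = "metseason_out"
    input_csv: str | None = None
    n_subjects: int = 2000
    window: tuple[tuple[int, int], tuple[int, int]] = ((2012, 4), (2017, 12))
    seed: int = 0
    trim_percentile: float = 0.005
    trim_by_sex: bool = False
    stl: StlConfig = field(default_factory=StlConfig)
    strata: bool = True
    make_plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        start = pd.Period(year=self.window[0][0], month=self.window[0][1], freq="M")
        end = pd.Period(year=self.window[1][0], month=self.window[1][1], freq="M")
        if (end - start).n + 1 < 24:
            raise ValueError("window must span at least two full years")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValueError(f"input_csv does not exist: {self.input_csv}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in raw:
            raw["window"] = tuple(tuple(x) for x in raw["window"])
        if "stl" in raw:
            raw["stl"] = StlConfig(**raw["stl"])
        raw.update(overrides)
        return cls(**raw)


def _decompose_series(series, config: StlConfig) -> Decomposition | None:
    try:
        return stl_decompose(series, config)
    except ValueError as err:
        log.warning("decomposition skipped: %s", err)
        return None


def _series_bundle(records: pd.DataFrame, window) -> dict[str, object]:
    """All monthly series analysed for one group of records."""
    out: dict[str, object] = {
        "prev_mets_jccms": monthly_prevalence(records, classify_jccms, window),
        "prev_mets_asian": monthly_prevalence(records, classify_asian, window),
    }
    flags = flag_markers(records)
    for marker in MARKERS:
        col = flags[marker].to_numpy()
        out[f"prev_{marker}"] = monthly_prevalence(records, lambda r, c=col: c, window)
        out[f"mean_{marker}"] = monthly_mean(records, marker, window)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle under ``outdir``."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- ingest -----------------------------------------------------------
    if config.input_csv is not None:
        records = read_cohort(config.input_csv)
        manifest = None
    else:
        spec = SeasonalModelSpec(
            n_subjects=config.n_subjects, window=config.window, seed=config.seed
        )
        records, manifest = generate_cohort(spec)
        write_cohort(records, outdir / "cohort.csv")
        manifest.to_json(outdir / "manifest.json")
    log.info("ingested %d records", len(records))

    # --- preprocess -------------------------------------------------------
    cleaning = CleaningConfig(
        trim_percentile=config.trim_percentile, stratify_by_sex=config.trim_by_sex
    )
    clean, reports = run_preprocess(records, cleaning)
    (outdir / "filter_reports.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2)
    )
    write_cohort(clean, outdir / "clean.csv")
    for r in reports:
        log.info("stage %-18s removed %6d of %7d records", r.stage, r.removed, r.n_in)

    # --- classification ---------------------------------------------------
    labels = classification_table(clean, JccmsThresholds(), AsianThresholds())
    labels.to_csv(outdir / "classification.csv", index=False)

    # --- monthly series, decomposition, summaries -------------------------
    decomp_rows, summary_rows, peak_rows = [], [], []
    decomps: dict[tuple[str, str], Decomposition] = {}

    groups: dict[str, pd.DataFrame] = {
        sex: clean.loc[clean["sex"] == sex] for sex in ("male", "female")
    }
    if config.strata:
        for key, grp in stratify(clean).items():
            groups[f"{key.sex}_{key.age_band}"] = grp

    for group_name, grp in groups.items():
        if grp.empty:
            continue
        for metric, series in _series_bundle(grp, config.window).items():
            decomp = _decompose_series(series, config.stl)
            if decomp is None:
                continue
            decomps[(group_name, metric)] = decomp
            frame = decomp.to_frame()
            frame.insert(0, "group", group_name)
            frame.insert(1, "metric", metric)
            decomp_rows.append(frame)
            summary = summarize_seasonal(decomp)
            sframe = summary.to_frame()
            sframe.insert(0, "group", group_name)
            sframe.insert(1, "metric", metric)
            summary_rows.append(sframe)
            peak_rows.append(
                {
                    "group": group_name,
                    "metric": metric,
                    "peak_month": summary.peak_month,
                    "trough_month": summary.trough_month,
                    "diff_mean": summary.diff_mean,
                    "diff_sd": summary.diff_sd,
                }
            )

    pd.concat(decomp_rows, ignore_index=True).to_csv(
        outdir / "decompositions.csv", index=False
    )
    pd.concat(summary_rows, ignore_index=True).to_csv(
        outdir / "seasonal_summary.csv", index=False
    )
    peaks = pd.DataFrame(peak_rows)
    peaks.to_csv(outdir / "peak_trough.csv", index=False)

    descriptives = season_descriptives(clean)
    descriptives.to_csv(outdir / "season_descriptives.csv", index=False)

    if config.make_plots:
        _write_plots(decomps, outdir)

    return {
        "records_in": len(records),
        "records_clean": len(clean),
        "manifest": manifest,
        "reports": reports,
        "decompositions": decomps,
        "peak_trough": peaks,
        "outdir": outdir,
    }


def _write_plots(decomps: dict, outdir: Path) -> None:
    """Observed + trend and per-year seasonal curves for headline metrics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (group, metric), decomp in decomps.items():
        if metric != "prev_mets_jccms" or "_" in group:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        x = decomp.series.periods.to_timestamp()
        axes[0].plot(x, decomp.observed, color="black", lw=1, label="observed")
        axes[0].plot(x, decomp.trend, color="red", lw=2, label="trend")
        axes[0].set_title(f"{group}: observed and secular trend")
        axes[0].set_ylabel("prevalence (%)")
        axes[0].legend()
        months = decomp.series.calendar_months
        years = decomp.series.years
        for yr in np.unique(years):
            sel = years == yr
            axes[1].plot(months[sel], decomp.seasonal[sel], lw=0.8, label=str(yr))
        summary = summarize_seasonal(decomp)
        axes[1].errorbar(
            np.arange(1, 13),
            summary.month_mean,
            yerr=summary.month_sd,
            color="black",
            lw=2,
        )
        axes[1].set_title(f"{group}: seasonal variation by year")
        axes[1].set_xlabel("calendar month")
        fig.tight_layout()
        fig.savefig(outdir / f"seasonal_{metric}_{group}.png", dpi=120)
        plt.close(fig)
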