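"""Metabolic-syndrome classification and per-marker out-of-range flags.

Two diagnostic rule sets are implemented:

* **JCCMS** (Japanese committee criteria): central obesity is mandatory —
  waist circumference >= 85 cm in men, >= 90 cm in women — plus at least
  two of (a) hypertension (SBP >= 130 mmHg and/or DBP >= 85 mmHg),
  (b) dyslipidemia (TG >= 150 mg/dL and/or HDL-C < 40 mg/dL),
  (c) insulin resistance (FPG >= 110 mg/dL).
* **Asian criteria**: at least three of five risk factors — WC >= 90 cm
  (men) / >= 80 cm (women); TG >= 150 mg/dL; HDL-C < 40 mg/dL (men) /
  < 50 mg/dL (women); SBP >= 130 and/or DBP >= 85 mmHg; FPG >= 100 mg/dL.

All comparisons are inclusive (>=) except the HDL-C cut, which is strict
(<), exactly as the criteria are printed.

Missing markers are handled with three-valued logic: a record is labelled
``mets`` or ``not_mets`` only when the observed markers already force that
outcome for every possible value of the missing ones; otherwise it is
``indeterminate`` and should be excluded from prevalence denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MET", "NOT_MET", "INDETERMINATE",
    "JccmsThresholds",
    "AsianThresholds",
    "flag_markers",
    "classify_jccms",
    "classify_asian",
    "classification_table",
]

MET = "mets"
NOT_MET = "not_mets"
INDETERMINATE = "indeterminate"


def _positive(**kv):
    for name, v in kv.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class JccmsThresholds:
    """Component cut-offs of the Japanese criteria (defaults as printed)."""

    wc_male: float = 85.0
    wc_female: float = 90.0
    sbp: float = 130.0
    dbp: float = 85.0
    tg: float = 150.0
    hdlc: float = 40.0  # strict: flagged when below
    fpg: float = 110.0

    def __post_init__(self) -> None:
        _positive(**{k: getattr(self, k) for k in
                     ("wc_male", "wc_female", "sbp", "dbp", "tg", "hdlc", "fpg")})


@dataclass(frozen=True)
class AsianThresholds:
    """Component cut-offs of the Asian five-factor criteria."""

    wc_male: float = 90.0
    wc_female: float = 80.0
    tg: float = 150.0
    hdlc_male: float = 40.0
    hdlc_female: float = 50.0
    sbp: float = 130.0
    dbp: float = 85.0
    fpg: float = 100.0

    def __post_init__(self) -> None:
        _positive(**{k: getattr(self, k) for k in
                     ("wc_male", "wc_female", "tg", "hdlc_male", "hdlc_female",
                      "sbp", "dbp", "fpg")})


def _marker_array(records: pd.DataFrame, col: str) -> np.ndarray:
    return records[col].to_numpy(dtype=float)


def _ge_flag(values: np.ndarray, cut) -> np.ndarray:
    """1.0 where value >= cut, 0.0 below, NaN where missing."""
    out = np.where(values >= cut, 1.0, 0.0)
    out[np.isnan(values)] = np.nan
    return out


def _lt_flag(values: np.ndarray, cut) -> np.ndarray:
    out = np.where(values < cut, 1.0, 0.0)
    out[np.isnan(values)] = np.nan
    return out


def _sex_cut(records: pd.DataFrame, male: float, female: float) -> np.ndarray:
    sex = records["sex"].to_numpy()
    cut = np.where(sex == "male", male, female)
    if not np.isin(sex, ("male", "female")).all():
        raise ValueError("sex must be 'male' or 'female' for every record")
    return cut


def flag_markers(
    records: pd.DataFrame, thresholds: JccmsThresholds | None = None
) -> pd.DataFrame:
    """Per-marker out-of-range flags under the JCCMS component cut-offs.

    Returns a frame with float columns ``wc``, ``sbp``, ``dbp``, ``tg``,
    ``hdlc``, ``fpg`` coded 1.0 (out of range), 0.0 (in range) or NaN
    (marker missing).  SBP and DBP are flagged separately.  Requires
    resolved blood-pressure columns.
    """
    th = thresholds or JccmsThresholds()
    return pd.DataFrame(
        {
            "wc": _ge_flag(_marker_array(records, "wc_cm"),
                           _sex_cut(records, th.wc_male, th.wc_female)),
            "sbp": _ge_flag(_marker_array(records, "sbp_mmhg"), th.sbp),
            "dbp": _ge_flag(_marker_array(records, "dbp_mmhg"), th.dbp),
            "tg": _ge_flag(_marker_array(records, "tg_mgdl"), th.tg),
            "hdlc": _lt_flag(_marker_array(records, "hdlc_mgdl"), th.hdlc),
            "fpg": _ge_flag(_marker_array(records, "fpg_mgdl"), th.fpg),
        },
        index=records.index,
    )


def _kleene_or(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Three-valued OR on 1/0/NaN flags."""
    out = np.full(a.shape, np.nan)
    out[(a == 1.0) | (b == 1.0)] = 1.0
    out[(a == 0.0) & (b == 0.0)] = 0.0
    return out


def _bounded_count(components: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper bound on the number of true components per record."""
    stack = np.vstack(components)
    n_true = np.nansum(stack == 1.0, axis=0)
    n_unknown = np.isnan(stack).sum(axis=0)
    return n_true, n_true + n_unknown


def classify_jccms(
    records: pd.DataFrame, thresholds: JccmsThresholds | None = None
) -> np.ndarray:
    """Tri-state JCCMS label per record (``mets``/``not_mets``/``indeterminate``).

    Central obesity is mandatory; a record without it is ``not_mets`` no
    matter what the other markers show.  With markers missing, the label
    is forced only when every completion of the missing values agrees.
    """
    flags = flag_markers(records, thresholds)
    obesity = flags["wc"].to_numpy()
    components = [
        _kleene_or(flags["sbp"].to_numpy(), flags["dbp"].to_numpy()),
        _kleene_or(flags["tg"].to_numpy(), flags["hdlc"].to_numpy()),
        flags["fpg"].to_numpy(),
    ]
    lo, hi = _bounded_count(components)
    labels = np.full(len(records), INDETERMINATE, dtype=object)
    labels[(obesity == 0.0) | (hi < 2)] = NOT_MET
    labels[(obesity == 1.0) & (lo >= 2)] = MET
    return labels


def classify_asian(
    records: pd.DataFrame, thresholds: AsianThresholds | None = None
) -> np.ndarray:
    """Tri-state Asian-criteria label: at least three of five risk factors."""
    th = thresholds or AsianThresholds()
    components = [
        _ge_flag(_marker_array(records, "wc_cm"),
                 _sex_cut(records, th.wc_male, th.wc_female)),
        _ge_flag(_marker_array(records, "tg_mgdl"), th.tg),
        _lt_flag(_marker_array(records, "hdlc_mgdl"),
                 _sex_cut(records, th.hdlc_male, th.hdlc_female)),
        _kleene_or(_ge_flag(_marker_array(records, "sbp_mmhg"), th.sbp),
                   _ge_flag(_marker_array(records, "dbp_mmhg"), th.dbp)),
        _ge_flag(_marker_array(records, "fpg_mgdl"), th.fpg),
    ]
    lo, hi = _bounded_count(components)
    labels = np.full(len(records), INDETERMINATE, dtype=object)
    labels[hi < 3] = NOT_MET
    labels[lo >= 3] = MET
    return labels


def classification_table(
    records: pd.DataFrame,
    jccms: JccmsThresholds | None = None,
    asian: AsianThresholds | None = None,
) -> pd.DataFrame:
    """Per-record flags plus both tri-state labels, ready to write as CSV."""
    flags = flag_markers(records, jccms)
    out = flags.copy()
    out.insert(0, "record_id", records["record_id"].to_numpy())
    out["jccms"] = classify_jccms(records, jccms)
    out["asian"] = classify_asian(records, asian)
    return out
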