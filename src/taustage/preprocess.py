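"""Amyloid harmonization, Aβ status, inclusion rules, meta-ROIs, age groups.

Amyloid PET SUVR is tracer-specific; the Centiloid scale is the standard
linear harmonization (≈0 for young controls, ≈100 for typical AD).  The
calibration coefficients are configuration, not logic: the defaults below are
representative published linear maps and can be overridden per tracer and per
cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TracerCalibration",
    "DEFAULT_CALIBRATIONS",
    "suvr_to_centiloid",
    "centiloid_to_suvr",
    "classify_abeta",
    "harmonize_amyloid",
    "centiloid_from_table",
    "apply_inclusion",
    "build_meta_roi",
    "assign_age_group",
    "AGE_GROUPS",
]

AGE_GROUPS = ("le65", "65to80", "gt80")


@dataclass(frozen=True)
class TracerCalibration:
    """Linear SUVR→Centiloid map and Aβ-positivity cutoff for one tracer."""

    tracer: str
    slope: float            # Centiloid per SUVR
    intercept: float        # Centiloid
    abeta_cutoff_suvr: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


# Published Centiloid conversions; Aβ+ cutoffs 1.11 (florbetapir) / 1.08
# (florbetaben) SUVR. All overridable via config.
DEFAULT_CALIBRATIONS: Mapping[str, TracerCalibration] = {
    "florbetapir": TracerCalibration("florbetapir", 188.22, -189.16, 1.11),
    "florbetaben": TracerCalibration("florbetaben", 157.15, -151.87, 1.08),
}


def _get_calib(tracer: str,
               calibrations: Mapping[str, TracerCalibration] | None
               ) -> TracerCalibration:
    table = DEFAULT_CALIBRATIONS if calibrations is None else calibrations
    try:
        return table[tracer]
    except KeyError:
        raise KeyError(f"no tracer calibration configured for {tracer!r}")


def suvr_to_centiloid(suvr, calib: TracerCalibration):
    """Linear, strictly monotone SUVR→Centiloid transform."""
    suvr = np.asarray(suvr, dtype=float)
    if np.any(suvr <= 0):
        raise ValueError("SUVR must be > 0")
    out = calib.slope * suvr + calib.intercept
    return float(out) if out.ndim == 0 else out


def centiloid_to_suvr(centiloid, calib: TracerCalibration):
    """Inverse of :func:`suvr_to_centiloid`."""
    cl = np.asarray(centiloid, dtype=float)
    out = (cl - calib.intercept) / calib.slope
    return float(out) if out.ndim == 0 else out


def classify_abeta(suvr, calib: TracerCalibration):
    """Aβ status from global amyloid SUVR: positive iff strictly above cutoff."""
    suvr = np.asarray(suvr, dtype=float)
    if np.any(suvr <= 0):
        raise ValueError("SUVR must be > 0")
    out = np.where(suvr > calib.abeta_cutoff_suvr, "pos", "neg")
    return str(out[()]) if out.ndim == 0 else out


def harmonize_amyloid(participants: pd.DataFrame,
                      calibrations: Mapping[str, TracerCalibration] | None = None
                      ) -> pd.DataFrame:
    """Add ``centiloid`` and ``abeta_status`` columns from per-tracer SUVR."""
    out = participants.copy()
    cl = np.empty(len(out))
    status = np.empty(len(out), dtype=object)
    for tracer in out["tracer"].unique():
        calib = _get_calib(tracer, calibrations)
        m = (out["tracer"] == tracer).to_numpy()
        s = out.loc[m, "amyloid_suvr"].to_numpy(dtype=float)
        cl[m] = suvr_to_centiloid(s, calib)
        status[m] = classify_abeta(s, calib)
    out["centiloid"] = cl
    out["abeta_status"] = status
    return out


def centiloid_from_table(participants: pd.DataFrame,
                         calibrations: Mapping[str, TracerCalibration] | None = None
                         ) -> np.ndarray:
    """Centiloid vector for a participant table (convenience)."""
    return harmonize_amyloid(participants, calibrations)["centiloid"].to_numpy()


def apply_inclusion(participants: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the clinical inclusion rule and return (kept, exclusion log).

    Amyloid-negative subjects with a diagnosis other than CN are excluded
    (their impairment cannot be attributed to AD pathology); all Aβ+ subjects
    and Aβ− CN subjects are retained. Idempotent.
    """
    if "abeta_status" not in participants.columns:
        raise ValueError("run harmonize_amyloid first (abeta_status missing)")
    drop = (participants["abeta_status"] == "neg") & \
           (participants["diagnosis"] != "CN")
    log = pd.DataFrame({
        "id": participants.loc[drop, "id"],
        "reason": "abeta_negative_with_" +
                  participants.loc[drop, "diagnosis"].astype(str),
    })
    return participants.loc[~drop].reset_index(drop=True), \
        log.reset_index(drop=True)


def build_meta_roi(tau_series: pd.DataFrame,
                   roi_set: Sequence[str],
                   name: str,
                   weights: Iterable[float] | None = None) -> pd.DataFrame:
    """Append a composite (meta) ROI series as the weighted mean of members.

    Equal weights by default. A visit missing any member ROI gets a missing
    meta value and a logged warning rather than an error.
    """
    roi_set = list(roi_set)
    if weights is None:
        w = np.full(len(roi_set), 1.0 / len(roi_set))
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (len(roi_set),):
            raise ValueError("weights must match roi_set length")
        w = w / w.sum()

    sub = tau_series[tau_series["roi"].isin(roi_set)]
    wide = sub.pivot_table(index=["id", "time"], columns="roi", values="suvr")
    missing = wide[roi_set].isna().any(axis=1)
    if missing.any():
        logger.warning("meta-ROI %s: %d visits missing a member ROI",
                       name, int(missing.sum()))
    meta = wide[roi_set].to_numpy() @ w
    meta[missing.to_numpy()] = np.nan
    out = wide.index.to_frame(index=False)
    out["roi"] = name
    out["suvr"] = meta
    return pd.concat([tau_series, out], ignore_index=True)


def assign_age_group(age):
    """Age stratification: ≤65 / (65, 80] / >80 years."""
    arr = np.asarray(age, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("age must be > 0")
    out = np.where(arr <= 65.0, "le65", np.where(arr <= 80.0, "65to80", "gt80"))
    if out.ndim == 0:
        return str(out[()])
    if isinstance(age, pd.Series):
        return pd.Series(out, index=age.index)
    return out
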