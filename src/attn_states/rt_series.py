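"""Construction of the per-run reaction-time series shared by all models.

All three attentional-state transforms consume a complete RT string: one
value per trial, including stop trials and omissions. This module handles
subject-level quality control, the RT validity rule (go trials with
RT > 150 ms, correct or not, including responses after the 1,000 ms
window), within-run z-scoring on the valid trials, linear interpolation
of the invalid trials on the z-scale, and temporal Gaussian smoothing
with a kernel defined over real onset times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RTSeries",
    "QCReport",
    "qc_subject",
    "extract_rt_series",
    "zscore_run",
    "interpolate_invalid",
    "gaussian_smooth_series",
]

MIN_VALID_RT_MS = 150.0
FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass
class RTSeries:
    """Per-run trial series.

    values are in ms before z-scoring and z-units after; invalid trials
    hold NaN until interpolation fills them. ``valid`` marks observed
    usable RTs, ``interpolated`` marks filled-in trials; the two masks
    are mutually exclusive.
    """

    run_id: int
    onsets_s: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray
    units: str = "ms"

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.onsets_s) == len(self.valid) == len(self.interpolated) == n):
            raise ValueError("field lengths differ")
        if np.any(self.valid & self.interpolated):
            raise ValueError("a trial cannot be both valid and interpolated")

    @property
    def complete(self) -> bool:
        return not np.any(np.isnan(self.values))

    def copy(self) -> "RTSeries":
        return RTSeries(self.run_id, self.onsets_s.copy(), self.values.copy(),
                        self.valid.copy(), self.interpolated.copy(), self.units)


@dataclass(frozen=True)
class QCReport:
    subject_id: str
    go_accuracy: float
    stop_probability: float
    retained: bool
    reason: str = ""


def qc_subject(runs: Sequence[pd.DataFrame], subject_id: str = "sub",
               min_go_accuracy: float = 0.66,
               stop_prob_bounds: tuple[float, float] = (0.25, 0.75)) -> QCReport:
    """Apply the behavioral inclusion rules, pooled over runs.

    go_accuracy = correct go responses / all go trials (omissions count
    against accuracy); stop_probability = successful stops / stop trials.
    A subject is retained iff go_accuracy >= 66% and stop probability
    lies in [25%, 75%].
    """
    if not runs or all(len(r) == 0 for r in runs):
        raise ValueError("no trials supplied")
    trials = pd.concat(runs, ignore_index=True)
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    if len(go) == 0 or len(stop) == 0:
        raise ValueError("need at least one go and one stop trial")
    go_acc = float((go["correct"] & go["responded"]).mean())
    stop_prob = float((~stop["responded"]).mean())

    reasons = []
    if go_acc < min_go_accuracy:
        reasons.append("go accuracy")
    if not (stop_prob_bounds[0] <= stop_prob <= stop_prob_bounds[1]):
        reasons.append("stop probability")
    return QCReport(subject_id, go_acc, stop_prob,
                    retained=not reasons, reason="; ".join(reasons))


def extract_rt_series(run: pd.DataFrame, run_id: int = 0,
                      min_rt_ms: float = MIN_VALID_RT_MS) -> RTSeries:
    """Build the raw (ms) series, flagging which trials carry usable RTs.

    Valid: go trials with an RT above ``min_rt_ms``, correct or
    incorrect, including responses landing after the response window.
    Invalid (to be interpolated later): all stop trials, go omissions,
    and go RTs at or below the threshold.
    """
    rt = run["rt_ms"].to_numpy(dtype=float)
    is_go = (run["trial_type"] == "go").to_numpy()
    responded = run["responded"].to_numpy(dtype=bool)
    valid = is_go & responded & (rt > min_rt_ms)
    if valid.sum() == 0:
        raise ValueError("run has no valid go RTs")
    values = np.where(valid, rt, np.nan)
    return RTSeries(run_id=run_id, onsets_s=run["onset_s"].to_numpy(dtype=float),
                    values=values, valid=valid,
                    interpolated=np.zeros(len(run), dtype=bool), units="ms")


def zscore_run(series: RTSeries, ddof: int = 0) -> RTSeries:
    """Z-score using the mean and SD of this run's valid RTs only
    (population SD by default); invalid entries stay missing."""
    if series.units != "ms":
        raise ValueError("expected an ms-unit series")
    vals = series.values[series.valid]
    if len(vals) < 2:
        raise ValueError("need >= 2 valid trials to z-score")
    sd = float(np.std(vals, ddof=ddof))
    if sd == 0.0:
        raise ValueError("valid RTs have zero variance")
    out = series.copy()
    out.values = (series.values - float(np.mean(vals))) / sd
    out.units = "z"
    return out


def interpolate_invalid(series: RTSeries) -> RTSeries:
    """Fill invalid trials by linear interpolation between the nearest
    valid neighbors on the trial-index grid; leading/trailing gaps take
    the nearest valid value. Idempotent on complete series."""
    if series.valid.sum() < 1:
        raise ValueError("need at least one valid trial")
    out = series.copy()
    gaps = ~series.valid & ~series.interpolated
    if gaps.any():
        idx = np.arange(len(series.values), dtype=float)
        known = series.valid | series.interpolated
        out.values[gaps] = np.interp(idx[gaps], idx[known], series.values[known])
        out.interpolated = out.interpolated | gaps
    return out


def gaussian_smooth_series(series: RTSeries, fwhm_s: float = 7.2) -> RTSeries:
    """Temporal Gaussian smoothing over real onset times.

    value_i' = sum_j w_ij v_j / sum_j w_ij with
    w_ij = exp(-(t_i - t_j)^2 / (2 sigma^2)), sigma = FWHM / sqrt(8 ln 2).
    Row normalization re-weights the truncated kernel near run edges so
    edge trials are not attenuated. fwhm_s = 0 is the identity.
    """
    if fwhm_s < 0:
        raise ValueError("fwhm_s must be >= 0")
    if not series.complete:
        raise ValueError("smoothing requires a complete (interpolated) series")
    if fwhm_s == 0:
        return series.copy()
    sigma = fwhm_s * FWHM_TO_SIGMA
    t = series.onsets_s
    w = np.exp(-0.5 * ((t[:, None] - t[None, :]) / sigma) ** 2)
    out = series.copy()
    out.values = (w @ series.values) / w.sum(axis=1)
    return out


def run_to_frame(run: pd.DataFrame, series: RTSeries) -> pd.DataFrame:
    """Tabular per-run export: trial index, onset, raw RT, value, masks."""
    return pd.DataFrame({
        "trial_index": np.arange(len(series.values)),
        "onset_s": series.onsets_s,
        "rt_ms": run["rt_ms"].to_numpy(dtype=float),
        "value": series.values,
        "units": series.units,
        "valid": series.valid.astype(int),
        "interpolated": series.interpolated.astype(int),
    })
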