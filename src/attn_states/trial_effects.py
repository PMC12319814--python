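"""Trial-level (beta-series) analysis.

A single GLM with one regressor per trial ("least squares all"): each
trial contributes a boxcar starting at its go-stimulus onset with
duration equal to its RT, convolved with the canonical double-gamma
HRF. The per-trial parameter estimates are aggregated to parcels,
correlated (go trials only) with each RT-model series within subject,
and the per-subject correlations summarized as a covariate-adjusted
Cohen's d per parcel and network.

Trials without an RT (stop trials, omissions) get a duration read off
the interpolated z series mapped back to milliseconds with the run's
valid-trial mean and SD, so every trial has a regressor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .bold_glm import CANONICAL_HRF, HRFSpec, sample_hrf

__all__ = [
    "TrialBetaMatrix",
    "build_trial_design",
    "estimate_trial_betas",
    "aggregate_parcels",
    "subject_rt_bold_correlation",
    "effect_size_table",
    "trial_durations_ms",
]

MICROTIME = 16  # sub-TR sampling factor for boxcar construction


@dataclass
class TrialBetaMatrix:
    """Per-trial parameter estimates, trials x units."""

    betas: np.ndarray
    trial_index: np.ndarray
    subject_id: str = ""
    ridge: bool = False
    condition_number: float = np.nan


def trial_durations_ms(run: pd.DataFrame, zvalues: np.ndarray,
                       mean_ms: float, sd_ms: float,
                       min_ms: float = 1.0) -> np.ndarray:
    """Duration (ms) per trial: the observed RT where one exists, else
    the interpolated z value mapped back through the run's valid-trial
    mean and SD (floored at ``min_ms``)."""
    rt = run["rt_ms"].to_numpy(dtype=float)
    imputed = mean_ms + np.asarray(zvalues, dtype=float) * sd_ms
    dur = np.where(np.isnan(rt), imputed, rt)
    return np.maximum(dur, min_ms)


def build_trial_design(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    tr_s: float,
    n_frames: int,
    hrf: HRFSpec = CANONICAL_HRF,
    t0_s: float = 0.0,
) -> np.ndarray:
    """frames x trials design: one HRF-convolved boxcar per trial.

    Boxcars are built on a microtime grid (TR / 16) so sub-TR durations
    are represented, convolved with the kernel sampled at microtime
    resolution, then sampled at the frame times.
    """
    onsets = np.asarray(onsets_s, dtype=float) - t0_s
    durations = np.asarray(durations_s, dtype=float)
    if len(onsets) != len(durations):
        raise ValueError("one duration per onset required")
    if len(np.unique(onsets)) != len(onsets):
        raise ValueError("overlapping identical onsets")
    if np.any(onsets < 0) or np.any(onsets > (n_frames - 1) * tr_s):
        raise ValueError("trial onset outside the run's frame grid")
    dt = tr_s / MICROTIME
    n_fine = n_frames * MICROTIME
    X_fine = np.zeros((n_fine, len(onsets)))
    for j, (on, du) in enumerate(zip(onsets, durations)):
        a = int(round(on / dt))
        b = max(a + 1, int(round((on + du) / dt)))
        X_fine[a:min(b, n_fine), j] = 1.0
    kernel = sample_hrf(hrf, dt)
    conv = sp_signal.fftconvolve(X_fine, kernel[:, None], axes=0)[:n_fine]
    return conv[::MICROTIME]


def estimate_trial_betas(
    residual_bold: np.ndarray,
    design: np.ndarray,
    subject_id: str = "",
    trial_index: np.ndarray | None = None,
    cond_threshold: float = 1e8,
    ridge_lambda: float = 1e-2,
) -> TrialBetaMatrix:
    """Joint OLS across all trial columns (intercept included).

    When the design is under-determined (frames <= trials) or severely
    collinear, an L2-regularized (ridge) solve is used instead and the
    result flagged.
    """
    Y = np.asarray(residual_bold, dtype=float)  # units x frames
    X = np.asarray(design, dtype=float)         # frames x trials
    n_frames, n_trials = X.shape
    if Y.shape[1] != n_frames:
        raise ValueError("design frame count does not match bold")
    if trial_index is None:
        trial_index = np.arange(n_trials)
    Xd = np.hstack([np.ones((n_frames, 1)), X])
    cond = float(np.linalg.cond(Xd))
    ridge = n_frames <= n_trials + 1 or cond > cond_threshold
    if ridge:
        warnings.warn("trial design ill-conditioned; using ridge fallback")
        XtX = Xd.T @ Xd
        lam = ridge_lambda * float(np.trace(XtX)) / XtX.shape[0]
        penalty = lam * np.eye(XtX.shape[0])
        penalty[0, 0] = 0.0  # never shrink the intercept
        coef = np.linalg.solve(XtX + penalty, Xd.T @ Y.T)
    else:
        coef, *_ = np.linalg.lstsq(Xd, Y.T, rcond=None)
    return TrialBetaMatrix(betas=coef[1:], trial_index=np.asarray(trial_index),
                           subject_id=subject_id, ridge=ridge,
                           condition_number=cond)


def aggregate_parcels(values: np.ndarray, labels: np.ndarray,
                      parcel_ids: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean of unit-level values per parcel.

    ``values`` may be a vector (units,) or a matrix (..., units);
    ``labels`` assigns each unit to a parcel id. Parcels with no units
    yield NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if parcel_ids is None:
        parcel_ids = np.unique(labels)
    flat = values.reshape(-1, values.shape[-1])
    out = np.full((flat.shape[0], len(parcel_ids)), np.nan)
    for k, pid in enumerate(parcel_ids):
        m = labels == pid
        if m.any():
            out[:, k] = flat[:, m].mean(axis=1)
    return out.reshape(values.shape[:-1] + (len(parcel_ids),))


def subject_rt_bold_correlation(trial_betas: TrialBetaMatrix,
                                series_values: np.ndarray,
                                trials: pd.DataFrame,
                                min_go_trials: int = 10) -> np.ndarray:
    """Per-parcel Pearson r between go-trial betas and the RT series.

    Restricted to go trials; parcels whose beta vector has zero variance
    return NaN.
    """
    s = np.asarray(series_values, dtype=float)
    if len(s) != len(trials) or trial_betas.betas.shape[0] != len(trials):
        raise ValueError("series, trials and betas must align")
    go = (trials["trial_type"] == "go").to_numpy()
    if go.sum() < min_go_trials:
        raise ValueError(f"need >= {min_go_trials} go trials")
    B = trial_betas.betas[go]          # go trials x parcels
    sv = s[go] - s[go].mean()
    s_norm = np.sqrt((sv ** 2).sum())
    Bc = B - B.mean(axis=0)
    b_norm = np.sqrt((Bc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Bc.T @ sv) / (b_norm * s_norm)
    r[(b_norm == 0)] = np.nan
    if s_norm == 0:
        r[:] = np.nan
    return r


def effect_size_table(
    r_matrix: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    parcellation: pd.DataFrame,
    model: str = "",
    d_definition: str = "intercept_over_sd",
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted Cohen's d per parcel.

    Per parcel, the per-subject correlations are regressed on an
    intercept plus centered age and a sex indicator; d is the intercept
    (the covariate-adjusted mean r) divided by the residual SD. The
    alternative ``d_definition='t_over_sqrt_n'`` uses the intercept's
    t statistic scaled by 1/sqrt(n). Constant covariates are dropped
    with a warning. Returns one row per parcel with its network label
    and the per-subject r summary.
    """
    R = np.asarray(r_matrix, dtype=float)
    n, n_parcels = R.shape
    if n < 3:
        raise ValueError("need >= 3 subjects")
    if n_parcels != len(parcellation):
        raise ValueError("r matrix width must equal parcel count")
    if fisher_z:
        R = np.arctanh(np.clip(R, -0.999999, 0.999999))
    cols = [np.ones(n)]
    for name, c in (("age", np.asarray(age, dtype=float)),
                    ("sex", np.asarray(sex, dtype=float))):
        if np.ptp(c) == 0:
            warnings.warn(f"constant covariate '{name}' dropped")
        else:
            cols.append(c - c.mean())
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise ValueError("need more subjects than covariate-model columns")
    xtx_inv = np.linalg.inv(X.T @ X)
    ok = ~np.isnan(R).any(axis=0)
    coef = np.full((p, n_parcels), np.nan)
    coef[:, ok] = xtx_inv @ X.T @ R[:, ok]
    resid = R - X @ np.nan_to_num(coef, nan=0.0)
    dof = n - p
    resid_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
    b0 = coef[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        if d_definition == "intercept_over_sd":
            d = b0 / resid_sd
            # degenerate zero-residual case: d = 0 for an exactly-zero mean
            d = np.where((resid_sd == 0) & (b0 == 0), 0.0, d)
        elif d_definition == "t_over_sqrt_n":
            se0 = resid_sd * math.sqrt(xtx_inv[0, 0])
            d = (b0 / se0) / math.sqrt(n)
        else:
            raise ValueError("unknown d_definition")
    d = np.where(ok, d, np.nan)
    return pd.DataFrame({
        "parcel_id": parcellation["parcel_id"].to_numpy(),
        "network": parcellation["network"].to_numpy(),
        "model": model,
        "cohens_d": d,
        "mean_r": R.mean(axis=0),
        "sd_r": R.std(axis=0, ddof=1),
        "n_subjects": n,
    })
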