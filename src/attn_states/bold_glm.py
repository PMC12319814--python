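"""Parcel/voxel-wise amplitude-modulated (AM) GLM pipeline.

Two-step procedure per run: (1) ordinary least squares removal of a
21-parameter nuisance model (6 rigid-body motion estimates, their first
derivatives and squares, plus white-matter, CSF and whole-brain mean
signals); (2) OLS fit of the residuals to the RT-model time series
placed as mean-centered amplitudes at trial onsets and convolved with a
hemodynamic response function. Run-level estimates are combined within
subject by fixed effects (inverse-variance weighting) and carried to a
group-level intercept test whose t statistics are mapped to z.

All fits are closed-form OLS vectorized across parcels; the same code
path serves flattened voxel matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats, special

from .synthetic import BoldRun

__all__ = [
    "HRFSpec",
    "GLMResult",
    "GroupMap",
    "sample_hrf",
    "preprocess_bold",
    "build_confound_matrix",
    "regress_nuisance",
    "build_am_regressor",
    "fit_am_glm",
    "combine_runs_fixed_effects",
    "group_level_glm",
]

Z_CAP = 40.0


@dataclass(frozen=True)
class HRFSpec:
    """Hemodynamic response kernel.

    kind 'gaussian': bump at ``peak_delay_s`` with ``width_param_s`` as
    FWHM (the kernel used for the AM regression). kind 'double_gamma':
    the canonical SPM-style difference of gammas (peak ~5-6 s, undershoot
    ~16 s); width_param_s is ignored. Kernels are peak-normalized.
    """

    kind: str = "gaussian"
    peak_delay_s: float = 5.0
    width_param_s: float = 5.0
    support_s: float = 16.0
    undershoot_delay_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "double_gamma"):
            raise ValueError("kind must be 'gaussian' or 'double_gamma'")
        if min(self.peak_delay_s, self.width_param_s, self.support_s) <= 0:
            raise ValueError("HRF parameters must be positive")


def sample_hrf(hrf: HRFSpec, dt_s: float) -> np.ndarray:
    """Sample the kernel on a grid with spacing ``dt_s`` over its support."""
    t = np.arange(0.0, hrf.support_s + dt_s / 2, dt_s)
    if hrf.kind == "gaussian":
        sigma = hrf.width_param_s / math.sqrt(8.0 * math.log(2.0))
        k = np.exp(-0.5 * ((t - hrf.peak_delay_s) / sigma) ** 2)
    else:
        # difference of gamma densities, shape/scale in seconds
        a1, a2, b = hrf.peak_delay_s + 1.0, hrf.undershoot_delay_s, 1.0
        g1 = t ** (a1 - 1) * np.exp(-t / b) / (b ** a1 * special.gamma(a1))
        g2 = t ** (a2 - 1) * np.exp(-t / b) / (b ** a2 * special.gamma(a2))
        k = g1 - hrf.undershoot_ratio * g2
    peak = np.abs(k).max()
    if peak == 0:
        raise ValueError("degenerate HRF kernel")
    return k / peak


CANONICAL_HRF = HRFSpec(kind="double_gamma", peak_delay_s=5.0, support_s=32.0)


@dataclass
class GLMResult:
    """Per-unit slope estimate for one regressor."""

    beta: np.ndarray
    var: np.ndarray
    tstat: np.ndarray
    dof: float
    regressor_label: str = ""

    @property
    def zstat(self) -> np.ndarray:
        return t_to_z(self.tstat, self.dof)


@dataclass
class GroupMap:
    model: str
    z: np.ndarray
    beta: np.ndarray
    n_subjects: int


def t_to_z(t: np.ndarray, dof: float, cap: float = Z_CAP) -> np.ndarray:
    """Map t statistics to standard-normal quantiles of equal tail
    probability, capped at +/-cap to guard against overflow."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        z = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), dof))
    z = np.where(np.isfinite(t), z, np.nan)
    return np.clip(z, -cap, cap)


def preprocess_bold(run: BoldRun, n_drop_frames: int = 8,
                    normalize: str = "mean100") -> BoldRun:
    """Drop initial frames (from signal and confound series alike) and
    normalize each unit's time-series. 'mean100' rescales every series
    to mean 100; 'none' leaves amplitudes untouched. The run's t0_s
    advances by n_drop_frames x TR so trial onsets stay aligned."""
    if n_drop_frames < 0:
        raise ValueError("n_drop_frames must be >= 0")
    if run.n_frames <= n_drop_frames:
        raise ValueError("cannot drop all frames")
    if normalize not in ("none", "mean100"):
        raise ValueError("normalize must be 'none' or 'mean100'")
    sig = run.signal[:, n_drop_frames:].astype(float, copy=True)
    if normalize == "mean100":
        mu = sig.mean(axis=1, keepdims=True)
        if np.any(mu == 0):
            raise ValueError("zero-mean series cannot be scaled to mean 100")
        sig = sig / mu * 100.0
    return BoldRun(
        signal=sig, tr_s=run.tr_s,
        motion=None if run.motion is None else run.motion[n_drop_frames:].copy(),
        tissue=None if run.tissue is None else run.tissue[n_drop_frames:].copy(),
        coupling=run.coupling, t0_s=run.t0_s + n_drop_frames * run.tr_s)


def build_confound_matrix(motion6: np.ndarray, tissue3: np.ndarray) -> np.ndarray:
    """21-column nuisance model: 6 motion parameters, their first
    temporal differences (zero-padded at the first frame), their
    squares, and the WM / CSF / whole-brain mean signals."""
    motion6 = np.asarray(motion6, dtype=float)
    tissue3 = np.asarray(tissue3, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion6 must be frames x 6")
    if tissue3.ndim != 2 or tissue3.shape[1] != 3:
        raise ValueError("tissue3 must be frames x 3 (WM, CSF, global)")
    if motion6.shape[0] != tissue3.shape[0]:
        raise ValueError("motion and tissue frame counts differ")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion6, axis=0)])
    return np.hstack([motion6, deriv, motion6 ** 2, tissue3])


def _design_with_intercept(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def regress_nuisance(bold: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS-residualize each unit's series against the confound columns
    (intercept always included). Collinear confound columns are dropped
    with a warning rather than failing."""
    bold = np.asarray(bold, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    n = bold.shape[1]
    if confounds.shape[0] != n:
        raise ValueError("confound frame count does not match bold")
    if n < confounds.shape[1] + 2:
        raise ValueError("too few frames for the confound model")
    X = _design_with_intercept(confounds)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy QR-style pruning of dependent columns
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        warnings.warn(f"dropping {X.shape[1] - len(keep)} collinear confound column(s)")
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, bold.T, rcond=None)
    return bold - (X @ beta).T


def build_am_regressor(
    series_values: np.ndarray,
    trial_onsets_s: np.ndarray,
    tr_s: float,
    hrf: HRFSpec,
    n_frames: int,
    t0_s: float = 0.0,
    mean_center: bool = True,
) -> np.ndarray:
    """Amplitude-modulated regressor on the frame grid.

    An impulse train carries one (mean-centered) model value per trial
    at the nearest frame to its onset; the train is convolved with the
    HRF kernel sampled at TR and truncated to the run length.
    """
    series_values = np.asarray(series_values, dtype=float)
    onsets = np.asarray(trial_onsets_s, dtype=float) - t0_s
    if len(series_values) != len(onsets):
        raise ValueError("one amplitude per trial required")
    if np.any(np.isnan(series_values)):
        raise ValueError("series must be complete")
    idx = np.rint(onsets / tr_s).astype(int)
    if np.any(idx < 0) or np.any(idx >= n_frames):
        raise ValueError("trial onset outside the run's frame grid")
    amps = series_values - series_values.mean() if mean_center else series_values
    impulses = np.zeros(n_frames)
    np.add.at(impulses, idx, amps)
    kernel = sample_hrf(hrf, tr_s)
    return np.convolve(impulses, kernel)[:n_frames]


def fit_am_glm(residual_bold: np.ndarray, am_regressor: np.ndarray,
               label: str = "") -> GLMResult:
    """Per-unit simple OLS of the residual series on the AM regressor
    (with intercept): slope, its sampling variance, and t."""
    Y = np.asarray(residual_bold, dtype=float)
    x = np.asarray(am_regressor, dtype=float)
    n = len(x)
    if Y.shape[1] != n:
        raise ValueError("regressor length does not match frames")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("zero-variance AM regressor")
    xc = x - x.mean()
    beta = (Y @ xc) / sxx
    fitted_mean = Y.mean(axis=1)
    resid = Y - fitted_mean[:, None] - beta[:, None] * xc[None, :]
    dof = n - 2
    sigma2 = (resid ** 2).sum(axis=1) / dof
    var = sigma2 / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, beta / np.sqrt(var), np.sign(beta) * np.inf)
    return GLMResult(beta=beta, var=var, tstat=t, dof=dof, regressor_label=label)


def combine_runs_fixed_effects(results: Sequence[GLMResult]) -> GLMResult:
    """Inverse-variance-weighted (fixed-effects) combination across runs:
    beta = sum(b_i / v_i) / sum(1 / v_i), var = 1 / sum(1 / v_i). Runs
    with non-finite variance for a unit get zero weight there."""
    if not results:
        raise ValueError("no run results")
    betas = np.stack([r.beta for r in results])
    vars_ = np.stack([r.var for r in results])
    w = np.where(np.isfinite(vars_) & (vars_ > 0), 1.0 / vars_, 0.0)
    wsum = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(wsum > 0, (w * np.nan_to_num(betas, nan=0.0)).sum(axis=0) / wsum, np.nan)
        var = np.where(wsum > 0, 1.0 / wsum, np.nan)
    dof = float(sum(r.dof for r in results))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(var)
    label = results[0].regressor_label
    return GLMResult(beta=beta, var=var, tstat=t, dof=dof, regressor_label=label)


def group_level_glm(subject_betas: np.ndarray,
                    covariates: np.ndarray | None = None,
                    model: str = "") -> GroupMap:
    """Group map from per-subject betas (subjects x units): per-unit
    OLS intercept test, optionally adjusting for covariate columns
    (e.g. centered age and a sex indicator); t mapped to z and capped."""
    B = np.asarray(subject_betas, dtype=float)
    if B.ndim != 2 or B.shape[0] < 3:
        raise ValueError("need a subjects x units matrix with >= 3 subjects")
    n = B.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([np.ones((n, 1)), C - C.mean(axis=0)])
    p = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ B
    resid = B - X @ coef
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se0 = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 0.0))
    b0 = coef[0]
    degenerate = se0 == 0
    if degenerate.any():
        warnings.warn("zero residual variance in some units; z capped")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.sign(b0) * np.inf, b0 / se0)
    z = t_to_z(np.where(np.isinf(t), np.sign(t) * 1e6, t), dof)
    return GroupMap(model=model, z=z, beta=b0, n_subjects=n)
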