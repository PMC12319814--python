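"""The three trial-level attentional-state time series.

Given the complete, z-scored, interpolated RT series of a subject:

* VTC (variance time course): |z| per trial, Gaussian-smoothed per run
  (7.2 s FWHM). High values mark deviant responding in either direction.
* z-score model: the signed z series, smoothed the same way. High values
  mark slow responding, low values fast responding.
* HMM model: the posterior probability of the longer-RT state from a
  two-state Gaussian HMM fitted to the unsmoothed series, runs
  concatenated per subject. No additional smoothing is applied.

Also implements the accuracy-by-model-value binning used to characterize
how each transform relates to go-trial performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm import HMMFit, fit_gaussian_hmm, forward_backward, viterbi
from .rt_series import RTSeries, gaussian_smooth_series

__all__ = [
    "AttentionSeries",
    "compute_vtc",
    "compute_zscore_model",
    "compute_hmm_model",
    "state_probability",
    "accuracy_by_series_bin",
    "fit_gaussian_hmm",
]

DEFAULT_FWHM_S = 7.2


@dataclass
class AttentionSeries:
    """Per-trial model values concatenated over runs.

    units: '|z|' for vtc (values >= 0), 'z' for zscore, 'probability'
    for hmm (values in [0, 1]). run_starts holds the index of each run's
    first trial.
    """

    model: str
    values: np.ndarray
    run_starts: np.ndarray
    units: str

    def per_run(self) -> list[np.ndarray]:
        bounds = list(self.run_starts) + [len(self.values)]
        return [self.values[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def _as_list(series: RTSeries | Sequence[RTSeries]) -> list[RTSeries]:
    return [series] if isinstance(series, RTSeries) else list(series)


def _check_complete(runs: list[RTSeries]) -> None:
    for s in runs:
        if not s.complete:
            raise ValueError("attentional models require complete (interpolated) series")
        if s.units != "z":
            raise ValueError("attentional models consume z-unit series")


def _run_starts(runs: list[RTSeries]) -> np.ndarray:
    lengths = [len(s.values) for s in runs]
    return np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int)


def compute_vtc(zseries: RTSeries | Sequence[RTSeries],
                fwhm_s: float = DEFAULT_FWHM_S) -> AttentionSeries:
    """Variance time course: absolute z-scores, smoothed per run."""
    runs = _as_list(zseries)
    _check_complete(runs)
    smoothed = []
    for s in runs:
        a = s.copy()
        a.values = np.abs(a.values)
        smoothed.append(gaussian_smooth_series(a, fwhm_s).values)
    return AttentionSeries("vtc", np.concatenate(smoothed), _run_starts(runs), "|z|")


def compute_zscore_model(zseries: RTSeries | Sequence[RTSeries],
                         fwhm_s: float = DEFAULT_FWHM_S) -> AttentionSeries:
    """Signed smoothed z-score series (the linear RT model)."""
    runs = _as_list(zseries)
    _check_complete(runs)
    smoothed = [gaussian_smooth_series(s, fwhm_s).values for s in runs]
    return AttentionSeries("zscore", np.concatenate(smoothed), _run_starts(runs), "z")


def compute_hmm_model(zseries: RTSeries | Sequence[RTSeries],
                      n_restarts: int = 10, tol: float = 1e-4,
                      max_iter: int = 500, seed: int | None = None
                      ) -> tuple[AttentionSeries, HMMFit]:
    """Fit the two-state Gaussian HMM on the concatenated z series and
    return the longer-RT-state posterior probability series (unsmoothed)
    together with the fit."""
    runs = _as_list(zseries)
    _check_complete(runs)
    x = np.concatenate([s.values for s in runs])
    fit = fit_gaussian_hmm(x, n_states=2, n_restarts=n_restarts,
                           tol=tol, max_iter=max_iter, seed=seed)
    series = AttentionSeries("hmm", fit.state_prob.copy(), _run_starts(runs), "probability")
    return series, fit


def state_probability(fit: HMMFit, zseries: RTSeries | Sequence[RTSeries]) -> AttentionSeries:
    """Posterior P(longer-RT state) per trial under a fitted model, via
    forward-backward on the supplied series. The fit is already
    canonically labeled (state 1 = longer mean RT), so the returned
    probabilities increase with RT."""
    runs = _as_list(zseries)
    _check_complete(runs)
    x = np.concatenate([s.values for s in runs])
    _, gamma, _ = forward_backward(x, fit.means, fit.variances,
                                   fit.transmat, fit.startprob)
    return AttentionSeries("hmm", gamma[:, -1], _run_starts(runs), "probability")


def viterbi_path(fit: HMMFit, zseries: RTSeries | Sequence[RTSeries]) -> np.ndarray:
    """Hard most-likely-state path under a fitted model."""
    runs = _as_list(zseries)
    _check_complete(runs)
    x = np.concatenate([s.values for s in runs])
    return viterbi(x, fit.means, fit.variances, fit.transmat, fit.startprob)


def accuracy_by_series_bin(
    series_per_subject: Sequence[AttentionSeries | np.ndarray],
    trials_per_subject: Sequence[pd.DataFrame],
    bin_edges: np.ndarray | None = None,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Go-trial accuracy as a function of model value.

    For each subject and bin, accuracy is computed over the go trials
    whose series value falls inside the bin (empty bins yield NaN, not
    an error). Returns (summary, per_subject): the summary carries the
    across-subject mean accuracy and standard error per bin.

    ``trials_per_subject[s]`` must be the subject's runs concatenated in
    series order. Default bin edges span the pooled value range.
    """
    values = [s.values if isinstance(s, AttentionSeries) else np.asarray(s)
              for s in series_per_subject]
    if len(values) != len(trials_per_subject):
        raise ValueError("series/trials length mismatch")
    if bin_edges is None:
        pooled = np.concatenate(values)
        bin_edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)

    rows = []
    for subj, (vals, trials) in enumerate(zip(values, trials_per_subject)):
        if len(vals) != len(trials):
            raise ValueError("series not aligned to trials")
        go = (trials["trial_type"] == "go").to_numpy()
        correct = (trials["correct"].astype(bool) & trials["responded"].astype(bool)).to_numpy()
        v, c = vals[go], correct[go]
        # rightmost edge inclusive so the max value is binned
        which = np.clip(np.digitize(v, bin_edges) - 1, 0, len(bin_edges) - 2)
        outside = (v < bin_edges[0]) | (v > bin_edges[-1])
        for b in range(len(bin_edges) - 1):
            m = (which == b) & ~outside
            rows.append({"subject": subj, "bin": b,
                         "bin_left": bin_edges[b], "bin_right": bin_edges[b + 1],
                         "n_trials": int(m.sum()),
                         "accuracy": float(c[m].mean()) if m.any() else np.nan})
    per_subject = pd.DataFrame(rows)
    g = per_subject.groupby("bin")
    summary = g.agg(bin_left=("bin_left", "first"), bin_right=("bin_right", "first"),
                    n_subjects=("accuracy", "count"),
                    mean_accuracy=("accuracy", "mean"),
                    sem_accuracy=("accuracy", "sem"),
                    n_trials=("n_trials", "sum")).reset_index()
    return summary, per_subject
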