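"""Synthetic stop-signal task (SST) behavior and coupled BOLD generator.

The generator mirrors the SST design used in large developmental imaging
studies: 2 runs x 180 trials, 30 stop trials per run (16.6%), a 1,000 ms
response window, a 700-2,000 ms jittered inter-trial interval, and an
adaptive stop-signal-delay (SSD) staircase starting at 50 ms that moves
+/-50 ms after every stop trial so that inhibition converges to ~50%.

Reaction times come from a hidden two-state Markov chain ("focused" fast
state vs "inattentive" slow state) with Gaussian emissions per state —
the generative mirror of the two-state Gaussian HMM fitted downstream.
Stop-trial outcomes follow the independent horse-race model: a response
is emitted iff the go finisher beats the stop finisher (RT < SSD + SSRT).

BOLD runs are produced by a forward model with known per-parcel coupling
to any trial-level amplitude series, so every downstream regression stage
can be validated against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SSTDesign",
    "AttentionGenParams",
    "BoldRun",
    "parabolic_error_fn",
    "simulate_subject",
    "step_ssd",
    "simulate_bold",
    "write_events_tsv",
    "write_bold_tsv",
]


@dataclass(frozen=True)
class SSTDesign:
    """Stop-signal task timing and staircase parameters (durations in ms)."""

    n_runs: int = 2
    n_trials_per_run: int = 180
    n_stop_per_run: int = 30
    response_window_ms: float = 1000.0
    iti_min_ms: float = 700.0
    iti_max_ms: float = 2000.0
    stim_duration_ms: float = 1000.0
    ssd_start_ms: float = 50.0
    ssd_step_ms: float = 50.0
    ssd_floor_ms: float = 0.0
    ssd_ceiling_ms: float = 900.0

    def __post_init__(self) -> None:
        if self.n_stop_per_run >= self.n_trials_per_run:
            raise ValueError("n_stop_per_run must be < n_trials_per_run")
        if self.iti_min_ms > self.iti_max_ms:
            raise ValueError("iti_min_ms must be <= iti_max_ms")
        if not (self.ssd_floor_ms <= self.ssd_start_ms <= self.ssd_ceiling_ms):
            raise ValueError("need ssd_floor <= ssd_start <= ssd_ceiling")
        for name in ("response_window_ms", "iti_min_ms", "stim_duration_ms",
                     "ssd_start_ms", "ssd_step_ms", "ssd_floor_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def parabolic_error_fn(
    rt_ms: np.ndarray | float,
    fast_ms: float = 450.0,
    slow_ms: float = 1200.0,
    floor: float = 0.04,
    peak: float = 0.8,
) -> np.ndarray:
    """U-shaped go-error probability: low for mid-range RTs, rising
    quadratically for very fast (<fast_ms) and very slow (>slow_ms)
    responses — impulsive errors on one end, lapses on the other."""
    rt = np.asarray(rt_ms, dtype=float)
    p = np.full(rt.shape, floor)
    fast = rt < fast_ms
    slow = rt > slow_ms
    p[fast] += (peak - floor) * np.minimum(1.0, ((fast_ms - rt[fast]) / 150.0) ** 2)
    p[slow] += (peak - floor) * np.minimum(1.0, ((rt[slow] - slow_ms) / 300.0) ** 2)
    return np.clip(p, 0.0, 0.95)


@dataclass(frozen=True)
class AttentionGenParams:
    """Parameters of the latent two-state attentional RT process.

    State 0 is the fast/"focused" state, state 1 the slow/"inattentive"
    one. ``stay_prob`` are the diagonal entries of the 2x2 transition
    matrix; ``ssrt_ms`` is the fixed stop-process latency used by the
    race model.
    """

    state_means_ms: tuple[float, float] = (520.0, 700.0)
    state_sds_ms: tuple[float, float] = (80.0, 120.0)
    stay_prob: tuple[float, float] = (0.9, 0.9)
    omission_prob: tuple[float, float] = (0.02, 0.10)
    error_fn: Callable[[np.ndarray], np.ndarray] = parabolic_error_fn
    ssrt_ms: float = 280.0

    def __post_init__(self) -> None:
        if not self.state_means_ms[0] < self.state_means_ms[1]:
            raise ValueError("fast-state mean must be below slow-state mean")
        if min(self.state_sds_ms) <= 0:
            raise ValueError("state SDs must be > 0")
        for p in (*self.stay_prob, *self.omission_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class BoldRun:
    """One run of parcellated BOLD data plus its generation ground truth.

    signal : (n_parcels, n_frames) array, arbitrary BOLD units
    motion : (n_frames, 6) rigid-body motion estimates
    tissue : (n_frames, 3) WM / CSF / whole-brain mean signals
    coupling : per-parcel forward-model weights (ground truth; None on
        real data)
    t0_s : acquisition time of the first retained frame relative to the
        trial-onset clock (advances when initial frames are dropped)
    """

    signal: np.ndarray
    tr_s: float = 0.8
    motion: np.ndarray | None = None
    tissue: np.ndarray | None = None
    coupling: np.ndarray | None = None
    t0_s: float = 0.0

    @property
    def n_parcels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]

    @property
    def frame_times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) * self.tr_s


def step_ssd(current_ssd_ms: float, stop_succeeded: bool, design: SSTDesign) -> float:
    """Adaptive staircase update: +step after a successful inhibition,
    -step after a failed one, clipped to [floor, ceiling]."""
    step = design.ssd_step_ms if stop_succeeded else -design.ssd_step_ms
    return float(np.clip(current_ssd_ms + step, design.ssd_floor_ms, design.ssd_ceiling_ms))


def _stationary_start(stay: tuple[float, float]) -> float:
    """P(state 1) under the chain's stationary distribution."""
    a, b = stay
    denom = (1.0 - a) + (1.0 - b)
    if denom == 0.0:  # absorbing chain: split evenly
        return 0.5
    return (1.0 - a) / denom


def simulate_subject(
    design: SSTDesign = SSTDesign(),
    gen: AttentionGenParams = AttentionGenParams(),
    seed: int = 0,
    carry_ssd: bool = False,
    allow_run_initial_stop: bool = False,
) -> list[pd.DataFrame]:
    """Simulate one subject's SST behavior.

    Returns one DataFrame per run with columns: trial_index, trial_type,
    onset_s, rt_ms (NaN when no response), responded, correct, ssd_ms
    (NaN on go trials), true_state.

    The SSD staircase restarts at ``ssd_start_ms`` for each run unless
    ``carry_ssd`` is set; stop-trial positions are uniform random, by
    default excluding the first trial of a run.
    """
    rng = np.random.default_rng(seed)
    runs: list[pd.DataFrame] = []
    ssd = design.ssd_start_ms
    state = int(rng.random() < _stationary_start(gen.stay_prob))

    for _ in range(design.n_runs):
        if not carry_ssd:
            ssd = design.ssd_start_ms
        first_allowed = 0 if allow_run_initial_stop else 1
        candidates = np.arange(first_allowed, design.n_trials_per_run)
        stop_pos = set(rng.choice(candidates, size=design.n_stop_per_run, replace=False))

        rows = []
        onset = 0.0
        for i in range(design.n_trials_per_run):
            is_stop = i in stop_pos
            # latent attentional chain advances every trial
            if rows:
                state = state if rng.random() < gen.stay_prob[state] else 1 - state
            go_rt = max(1.0, rng.normal(gen.state_means_ms[state], gen.state_sds_ms[state]))
            omitted = rng.random() < gen.omission_prob[state]

            if is_stop:
                # race model: a response escapes iff the go process
                # finishes before SSD + SSRT (and was not omitted)
                responded = (not omitted) and (go_rt < ssd + gen.ssrt_ms)
                rt = go_rt if responded else np.nan
                correct = not responded
                rows.append((i, "stop", onset, rt, responded, correct, ssd, state))
                ssd = step_ssd(ssd, stop_succeeded=not responded, design=design)
            else:
                responded = not omitted
                rt = go_rt if responded else np.nan
                if responded:
                    correct = rng.random() >= float(np.asarray(gen.error_fn(np.array([go_rt])))[0])
                else:
                    correct = False
                rows.append((i, "go", onset, rt, responded, correct, np.nan, state))

            iti = rng.uniform(design.iti_min_ms, design.iti_max_ms)
            onset += (design.response_window_ms + iti) / 1000.0

        runs.append(pd.DataFrame(
            rows,
            columns=["trial_index", "trial_type", "onset_s", "rt_ms",
                     "responded", "correct", "ssd_ms", "true_state"],
        ))
    return runs


def _gaussian_hrf_kernel(tr_s: float, peak_delay_s: float = 5.0,
                         fwhm_s: float = 5.0, support_s: float = 16.0) -> np.ndarray:
    t = np.arange(0.0, support_s + tr_s / 2, tr_s)
    sigma = fwhm_s / math.sqrt(8.0 * math.log(2.0))
    k = np.exp(-0.5 * ((t - peak_delay_s) / sigma) ** 2)
    return k / k.max()


def simulate_bold(
    runs: Sequence[pd.DataFrame],
    series_per_run: Sequence[np.ndarray],
    coupling: np.ndarray,
    noise_sd: float = 1.0,
    tr_s: float = 0.8,
    baseline: float = 100.0,
    confound_leak: float = 0.0,
    hrf_kernel: np.ndarray | None = None,
    seed: int = 0,
) -> list[BoldRun]:
    """Forward model: parcel signal = baseline + coupling x HRF-convolved
    amplitude-modulated regressor (+ optional confound leakage + white
    noise). ``series_per_run[r]`` supplies one amplitude per trial of run
    ``r``; amplitudes are mean-centered per run before convolution so the
    coupled component carries modulation, not mean response.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    coupling = np.asarray(coupling, dtype=float)
    rng = np.random.default_rng(seed)
    if hrf_kernel is None:
        hrf_kernel = _gaussian_hrf_kernel(tr_s)
    support_s = (len(hrf_kernel) - 1) * tr_s

    out: list[BoldRun] = []
    for trials, series in zip(runs, series_per_run):
        series = np.asarray(series, dtype=float)
        if len(series) != len(trials):
            raise ValueError("series length must equal trial count")
        onsets = trials["onset_s"].to_numpy()
        n_frames = int(math.ceil((onsets[-1] + support_s) / tr_s)) + 1

        amps = series - series.mean()
        impulses = np.zeros(n_frames)
        idx = np.rint(onsets / tr_s).astype(int)
        np.add.at(impulses, idx, amps)
        reg = np.convolve(impulses, hrf_kernel)[:n_frames]

        # smooth pseudo-motion (AR(1)) and tissue-mean nuisance series
        motion = np.zeros((n_frames, 6))
        innov = rng.normal(0.0, 0.02, size=(n_frames, 6))
        for t in range(1, n_frames):
            motion[t] = 0.95 * motion[t - 1] + innov[t]
        tissue = baseline + rng.normal(0.0, 0.5, size=(n_frames, 3))

        signal = baseline + np.outer(coupling, reg)
        if confound_leak:
            leak = motion.sum(axis=1) + (tissue - baseline).sum(axis=1)
            signal = signal + confound_leak * leak[None, :]
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        out.append(BoldRun(signal=signal, tr_s=tr_s, motion=motion,
                           tissue=tissue, coupling=coupling.copy()))
    return out


# ---------------------------------------------------------------------------
# BIDS-style text export

def write_events_tsv(run: pd.DataFrame, path: str | Path,
                     design: SSTDesign = SSTDesign(),
                     sidecar: bool = True) -> None:
    """Write one run as a BIDS-style events TSV (seconds; 'n/a' for
    missing values) plus a ground-truth sidecar TSV with the latent state."""
    path = Path(path)
    ev = pd.DataFrame({
        "onset": run["onset_s"].round(4),
        "duration": design.response_window_ms / 1000.0,
        "trial_type": run["trial_type"],
        "response_time": (run["rt_ms"] / 1000.0).round(4),
        "correct": run["correct"].astype(int),
        "ssd": (run["ssd_ms"] / 1000.0).round(4),
    })
    ev.to_csv(path, sep="\t", index=False, na_rep="n/a")
    if sidecar:
        gt = run[["trial_index", "true_state"]]
        gt.to_csv(path.with_suffix("").as_posix() + "_truth.tsv", sep="\t", index=False)


def write_bold_tsv(bold: BoldRun, path: str | Path, seed: int | None = None) -> None:
    """Write parcellated BOLD as frames x parcels TSV with a JSON sidecar
    recording tr_s, the generating coupling vector and the seed."""
    path = Path(path)
    cols = [f"parcel{i:04d}" for i in range(bold.n_parcels)]
    pd.DataFrame(bold.signal.T, columns=cols).to_csv(path, sep="\t", index=False)
    meta = {
        "tr_s": bold.tr_s,
        "t0_s": bold.t0_s,
        "coupling": None if bold.coupling is None else list(map(float, bold.coupling)),
        "seed": seed,
    }
    Path(path.with_suffix(".json")).write_text(json.dumps(meta, indent=1))
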