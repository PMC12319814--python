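"""End-to-end orchestration: behavior -> RT series -> attentional models
-> AM-GLM maps -> trial-level effects, for one subject or a simulated
group study with known ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import rt_series as rts
from .attn_models import (AttentionSeries, compute_hmm_model,
                          compute_vtc, compute_zscore_model)
from .bold_glm import (GLMResult, GroupMap, HRFSpec, build_am_regressor,
                       build_confound_matrix, combine_runs_fixed_effects,
                       fit_am_glm, group_level_glm, preprocess_bold,
                       regress_nuisance)
from .hmm import HMMFit
from .parcellation import gordon_like_parcellation
from .synthetic import (AttentionGenParams, BoldRun, SSTDesign,
                        simulate_bold, simulate_subject)
from .trial_effects import (TrialBetaMatrix, build_trial_design,
                            effect_size_table, estimate_trial_betas,
                            subject_rt_bold_correlation, trial_durations_ms)

__all__ = [
    "SubjectModels",
    "prepare_zseries",
    "compute_models",
    "subject_am_map",
    "subject_trial_betas",
    "StudyResult",
    "simulate_study",
]

MODEL_NAMES = ("vtc", "zscore", "hmm")


@dataclass
class SubjectModels:
    zseries: list[rts.RTSeries]
    series: dict[str, AttentionSeries]
    hmm_fit: HMMFit

    @property
    def trials(self) -> pd.DataFrame:
        raise AttributeError("trial tables are kept by the caller")


def prepare_zseries(runs: Sequence[pd.DataFrame]) -> list[rts.RTSeries]:
    """Raw trials -> valid-RT extraction -> within-run z-scoring ->
    interpolation of stop/omission/fast-RT trials, per run."""
    out = []
    for i, run in enumerate(runs):
        s = rts.extract_rt_series(run, run_id=i)
        s = rts.zscore_run(s)
        out.append(rts.interpolate_invalid(s))
    return out


def compute_models(zruns: Sequence[rts.RTSeries], fwhm_s: float = 7.2,
                   hmm_restarts: int = 10, hmm_seed: int | None = 0) -> SubjectModels:
    """All three attentional-state series for one subject."""
    vtc = compute_vtc(zruns, fwhm_s)
    zsc = compute_zscore_model(zruns, fwhm_s)
    hmm_series, fit = compute_hmm_model(zruns, n_restarts=hmm_restarts, seed=hmm_seed)
    return SubjectModels(zseries=list(zruns),
                         series={"vtc": vtc, "zscore": zsc, "hmm": hmm_series},
                         hmm_fit=fit)


def subject_am_map(
    bold_runs: Sequence[BoldRun],
    trial_runs: Sequence[pd.DataFrame],
    series: AttentionSeries,
    hrf: HRFSpec = HRFSpec(),
    n_drop_frames: int = 0,
    normalize: str = "none",
) -> GLMResult:
    """Two-step AM regression per run, fixed-effects combined.

    Synthetic runs carry no pre-steady-state frames, so no frames are
    dropped by default; real data should use n_drop_frames=8 and
    'mean100' normalization.
    """
    per_run = []
    for bold, trials, vals in zip(bold_runs, trial_runs, series.per_run()):
        b = preprocess_bold(bold, n_drop_frames, normalize)
        resid = b.signal
        if b.motion is not None and b.tissue is not None:
            conf = build_confound_matrix(b.motion, b.tissue)
            resid = regress_nuisance(resid, conf)
        reg = build_am_regressor(vals, trials["onset_s"].to_numpy(), b.tr_s,
                                 hrf, b.n_frames, t0_s=b.t0_s)
        per_run.append(fit_am_glm(resid, reg, label=series.model))
    return combine_runs_fixed_effects(per_run)


def subject_trial_betas(
    bold_runs: Sequence[BoldRun],
    trial_runs: Sequence[pd.DataFrame],
    zruns: Sequence[rts.RTSeries],
    n_drop_frames: int = 0,
    normalize: str = "none",
    subject_id: str = "",
) -> TrialBetaMatrix:
    """Per-trial (least-squares-all) betas, runs concatenated.

    Trial durations are the observed RTs, with stop/omission trials
    imputed from the interpolated z series via the run's valid-RT mean
    and SD.
    """
    blocks, ridge, conds = [], False, []
    for bold, trials, z in zip(bold_runs, trial_runs, zruns):
        b = preprocess_bold(bold, n_drop_frames, normalize)
        resid = b.signal
        if b.motion is not None and b.tissue is not None:
            conf = build_confound_matrix(b.motion, b.tissue)
            resid = regress_nuisance(resid, conf)
        rt_valid = trials["rt_ms"].to_numpy(dtype=float)
        valid = z.valid
        mean_ms = float(np.nanmean(rt_valid[valid]))
        sd_ms = float(np.nanstd(rt_valid[valid]))
        dur_ms = trial_durations_ms(trials, z.values, mean_ms, sd_ms)
        X = build_trial_design(trials["onset_s"].to_numpy(), dur_ms / 1000.0,
                               b.tr_s, b.n_frames, t0_s=b.t0_s)
        res = estimate_trial_betas(resid, X, subject_id=subject_id)
        blocks.append(res.betas)
        ridge = ridge or res.ridge
        conds.append(res.condition_number)
    betas = np.vstack(blocks)
    return TrialBetaMatrix(betas=betas, trial_index=np.arange(betas.shape[0]),
                           subject_id=subject_id, ridge=ridge,
                           condition_number=float(np.nanmax(conds)))


@dataclass
class StudyResult:
    """Ground-truth-coupled simulated group study."""

    parcellation: pd.DataFrame
    coupling: np.ndarray
    group_maps: dict[str, GroupMap]
    effect_tables: dict[str, pd.DataFrame]
    subject_models: list[SubjectModels]
    subject_trials: list[list[pd.DataFrame]]
    hmm_converged: list[bool] = field(default_factory=list)


def network_coupling(parcellation: pd.DataFrame, c: float,
                     positive: str = "DorsalAttn",
                     negative: str = "Default") -> np.ndarray:
    """+c for one network's parcels, -c for another's, 0 elsewhere —
    the synthetic analog of a task-positive/DMN-negative pattern."""
    net = parcellation["network"].to_numpy()
    return np.where(net == positive, c, np.where(net == negative, -c, 0.0))


def simulate_study(
    n_subjects: int = 20,
    coupling: np.ndarray | None = None,
    design: SSTDesign = SSTDesign(),
    gen: AttentionGenParams = AttentionGenParams(),
    couple_to: str = "zscore",
    noise_sd: float = 1.0,
    coupling_strength: float = 2.0,
    fwhm_s: float = 7.2,
    hmm_restarts: int = 3,
    with_trial_effects: bool = True,
    seed: int = 0,
) -> StudyResult:
    """Simulate a group study with known per-parcel coupling.

    Each subject's BOLD is generated from their own ``couple_to`` model
    series (so the coupled signal is behaviorally realistic); all three
    models are then estimated blind to the truth, run through the AM-GLM
    to group maps, and (optionally) through the trial-level pathway to
    covariate-adjusted effect-size tables.
    """
    rng = np.random.default_rng(seed)
    parc = gordon_like_parcellation()
    if coupling is None:
        coupling = network_coupling(parc, coupling_strength)

    subject_models: list[SubjectModels] = []
    subject_trials: list[list[pd.DataFrame]] = []
    betas = {m: [] for m in MODEL_NAMES}
    rmat = {m: [] for m in MODEL_NAMES}
    converged = []
    for s in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        runs = simulate_subject(design, gen, seed=sub_seed)
        zruns = prepare_zseries(runs)
        models = compute_models(zruns, fwhm_s=fwhm_s,
                                hmm_restarts=hmm_restarts, hmm_seed=sub_seed)
        converged.append(models.hmm_fit.converged)
        bold = simulate_bold(runs, models.series[couple_to].per_run(), coupling,
                             noise_sd=noise_sd, seed=sub_seed + 1)
        for m in MODEL_NAMES:
            res = subject_am_map(bold, runs, models.series[m])
            betas[m].append(res.beta)
        if with_trial_effects:
            tb = subject_trial_betas(bold, runs, zruns, subject_id=f"sub{s:03d}")
            trials_all = pd.concat(runs, ignore_index=True)
            for m in MODEL_NAMES:
                rmat[m].append(subject_rt_bold_correlation(
                    tb, models.series[m].values, trials_all))
        subject_models.append(models)
        subject_trials.append(runs)

    age = rng.normal(9.9, 0.6, size=n_subjects)
    sex = rng.integers(0, 2, size=n_subjects).astype(float)
    group_maps = {m: group_level_glm(np.stack(betas[m]), model=m)
                  for m in MODEL_NAMES}
    effect_tables = {}
    if with_trial_effects:
        effect_tables = {m: effect_size_table(np.stack(rmat[m]), age, sex,
                                              parc, model=m)
                         for m in MODEL_NAMES}
    return StudyResult(parcellation=parc, coupling=coupling,
                       group_maps=group_maps, effect_tables=effect_tables,
                       subject_models=subject_models,
                       subject_trials=subject_trials,
                       hmm_converged=converged)
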