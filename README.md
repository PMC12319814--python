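# attn-states

Trial-level reaction-time-variability (RTV) models and their BOLD
correlates for stop-signal task (SST) data.

## The problem

Intra-individual variability in reaction times — episodic slow (or very
fast) responses within a session — is a behavioral marker of fluctuating
attention. Several transforms turn a subject's trial-by-trial RT string
into a continuous "attentional state" series, and those series are then
related to brain activity. This package implements, end to end and with
a fully synthetic test bed, the three standard transforms and the
imaging pipelines around them:

- **VTC (variance time course)** — within-run z-scored RTs, absolute
  value, Gaussian-smoothed over time (7.2 s FWHM):
  `VTC_i = smooth(|z_i|)`. High values mark deviant responding in either
  direction.
- **z-score model** — the signed smoothed series `smooth(z_i)`: high =
  slow (lapse-like), low = fast (impulsive-like).
- **Two-state Gaussian HMM** — RTs are emissions of a latent two-state
  Markov chain; Baum–Welch learns the state means `μ_k`, variances
  `σ_k²` and the transition matrix `A`, and the forward–backward
  posterior `P(state = slow | z_1..z_T)` is the per-trial series
  (relabeled so state 1 is always the longer-RT state).

All three consume one complete RT value per trial: go trials with
RT > 150 ms are observed (correct or not, including responses after the
1,000 ms window); stop trials, omissions and too-fast responses are
filled by linear interpolation of the neighboring z-scores.

On the imaging side the package provides the amplitude-modulated (AM)
GLM pathway — 21-parameter nuisance regression (6 motion + derivatives
+ squares + WM/CSF/global), AM regression of the residuals on the
HRF-convolved model series, fixed-effects (inverse-variance) run
combination, group-level t→z maps — and the trial-level pathway — one
HRF-convolved regressor per trial (duration = RT), per-trial betas,
parcel aggregation, per-subject Pearson correlations between go-trial
betas and each model series, and covariate-adjusted Cohen's *d* per
parcel/network. Map comparison offers thresholded Dice overlap, percent
network coverage, and map-to-map correlations tested against shuffle or
variogram-matching (autocorrelation-preserving) permutation nulls.

Because the behavioral generator knows its ground truth (hidden state
sequence, per-parcel BOLD coupling), every stage is testable without any
data download: the simulator reproduces the SST design used in large
developmental studies (2 runs × 180 trials, 30 stop trials/run, 700–
2,000 ms jittered ITI, SSD staircase starting at 50 ms with ±50 ms
steps, race-model stop outcomes).

## Worked example

```python
import numpy as np
from attn_states import (SSTDesign, AttentionGenParams, simulate_subject,
                         qc_subject, threshold_map, dice_score)
from attn_states.pipeline import prepare_zseries, compute_models, simulate_study

# one synthetic subject: behavior, QC, the three model series
runs = simulate_subject(SSTDesign(), AttentionGenParams(), seed=1)
qc = qc_subject(runs)
zruns = prepare_zseries(runs)
models = compute_models(zruns, hmm_seed=1)

# a 20-subject study with +2/0/−2 coupling by network
study = simulate_study(n_subjects=20, seed=11)
```

Output (verbatim):

```
go accuracy = 0.863, stop probability = 0.600, retained = True
HMM emission means (z) = [-0.592  0.726]
HMM stay probabilities = [0.87  0.844]
corr(HMM state probability, z) = 0.81
display threshold z = 7.9
Dice+(zscore, hmm) = 1.00
Dice+(vtc, zscore) = 0.00
Dice+(vtc, hmm) = 0.00
vtc    median d: DorsalAttn = 1.05, Default = -1.03
zscore median d: DorsalAttn = 6.35, Default = -6.32
hmm    median d: DorsalAttn = 5.64, Default = -5.80
```

Reading this: the subject passes the behavioral inclusion rules
(go accuracy ≥ 66%, stop probability within 25–75%); the HMM recovers a
fast and a slow state with sticky transitions, and its posterior
probability series rises with RT as intended. In the simulated study —
where BOLD is coupled positively to the z-score series in dorsal
attention parcels and negatively in default-mode parcels — the group
maps of the z-score and HMM models agree almost perfectly at a strict
display threshold, while the VTC map (which discards the sign of the
RT deviation) overlaps far less; the effect-size tables recover the
task-positive/task-negative network pattern in all three models, with
the z-score model strongest.

## Layout

- `attn_states.synthetic` — SST behavior generator (staircase, race
  model, latent two-state RT process) and ground-truth BOLD forward model
- `attn_states.rt_series` — QC, RT validity, z-scoring, interpolation,
  temporal smoothing
- `attn_states.attn_models` — VTC / z-score / HMM series, accuracy-by-bin
- `attn_states.hmm` — Baum–Welch, forward–backward, Viterbi
- `attn_states.bold_glm` — nuisance + AM regression, fixed effects,
  group maps
- `attn_states.trial_effects` — trial-wise betas, parcel aggregation,
  effect sizes
- `attn_states.map_compare` — Dice, network coverage, spatial nulls
- `attn-states` CLI — `simulate`, `glm`, `compare`

See `docs/methods.md` for the modeling details and design choices.
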