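# Methods

## Synthetic stop-signal task behavior

The generator mirrors the SST design of large developmental imaging
studies: 2 runs of 180 trials, 30 stop trials per run (16.6%), a
1,000 ms response window followed by a jittered 700–2,000 ms ITI
(uniform), and an adaptive stop-signal-delay staircase that starts at
50 ms and moves +50 ms after a successful inhibition and −50 ms after a
failed one. Stop-trial positions are uniform random within a run,
excluding the run-initial trial (ordering is not constrained by the
design; the exclusion avoids a stop trial before any go behavior
exists). The staircase is clipped to [0, 900] ms: the floor is
physically forced, and the ceiling keeps the stop signal inside the
response window. The SSD restarts at 50 ms each run by default
(`carry_ssd` continues it across runs).

Reaction times come from a hidden two-state Markov chain with Gaussian
emissions — the generative mirror of the two-state HMM fitted
downstream. Defaults: state means 520/700 ms, SDs 80/120 ms,
self-transition probabilities 0.9/0.9, per-state omission probabilities
0.02/0.10. These were chosen once as plausible values for 9–10-year-old
SST behavior: a grand-mean RT near 600 ms, dwell times of ~10 trials
(~25 s) per attentional episode, and an overall omission rate near 6%,
which together with the 16.6% stop trials puts the interpolated-trial
fraction in the low-20% range. Gaussian draws are floored at 1 ms.

Go-trial accuracy uses a U-shaped error curve over RT: a floor of 4%
everywhere, rising quadratically below 450 ms (impulsive errors,
saturating at 80% by 300 ms) and above 1,200 ms (lapse errors). Both
thresholds are configurable; the defaults yield ~8% incorrect go
responses. Note that under the default RT distribution the slow arm
(>1,200 ms) is almost never reached — the qualitative "slow errors"
regime can be exercised by lowering `slow_ms` toward the generator's
own scale, as the binning tests do.

Stop outcomes follow the independent horse-race model with a fixed
stop-signal reaction time (SSRT, default 280 ms): a response escapes
iff the go finisher beats SSD + SSRT. Omitted trials never respond and
therefore count as successful stops. At equilibrium the staircase
tracks the SSD at which P(RT < SSD + SSRT) = 0.5, i.e. SSD ≈ median RT
− SSRT (~290 ms here, comfortably inside the clip range), giving the
designed ~50% inhibition rate. A fresh run's climb from 50 ms to
equilibrium takes ~5 staircase steps, so short runs are slightly
success-biased; the long-run rate is measured on a single continuous
staircase.

## RT series construction

Usable RTs are go-trial responses above 150 ms — correct or incorrect,
including responses after the response window. All stop trials, go
omissions and ≤150 ms responses are gap-filled. Z-scoring uses the mean
and SD of the run's valid trials only (population SD, divisor n; a
`ddof` switch gives the sample convention) — interpolated values are
functions of the valid z-scores, so including them would bias the
scale. Interpolation is linear on the trial-index grid between the
nearest valid neighbors; leading/trailing gaps take the nearest valid
value. (Index-grid interpolation follows the VTC lineage; the operation
is exposed separately so a time-based variant can be composed if
needed.) Interpolation is idempotent.

Temporal smoothing is a normalized Gaussian kernel over real onset
times, σ = FWHM/√(8 ln 2) with FWHM defaulting to 7.2 s. Row
normalization of the (implicitly truncated) kernel prevents edge
attenuation; smoothing therefore never extends the value range. FWHM 0
is the identity.

## The three attentional-state series

VTC = per-run smoothing of |z|; z-score model = per-run smoothing of z;
the two are identical where z ≥ 0 and mirror images where z ≤ 0 before
smoothing. The HMM consumes the unsmoothed, interpolated z series with
runs concatenated per subject (a per-run split is possible by calling
the fitter per run) and no smoothing is applied to its output
probability series.

The HMM is fitted by Baum–Welch with scaled forward–backward
recursions, written in-package so that the fit exposes a per-iteration
log-likelihood trace (nondecreasing by EM monotonicity), exact
`max_iter = 0` no-op semantics, and the scaled recursions themselves;
`hmmlearn` — the implementation the field typically reaches for — is
used in the test suite as an independent cross-check and agrees to
~1e-4 in final log-likelihood on shared data. Fitting details: 10
random restarts (best final log-likelihood wins), means initialized at
random data quantiles, shared data variance, diagonally dominant random
transition matrices; variance floor 1e-4 against single-point collapse;
convergence when |ΔLL| < 1e-4 within 500 iterations. Non-convergence is
reported on the fit (subjects can be dropped on it, mirroring the
behavioral QC rules). After fitting, states are relabeled so state 1
has the longer mean RT; the continuous series is the forward–backward
posterior P(state 1) — the only construct that yields a probability at
every trial — with the Viterbi path exposed separately.

Accuracy-by-bin tables compute, per subject and value bin, go-trial
accuracy (omissions count as incorrect), then mean ± SEM across
subjects. Empty bins are missing values, not errors.

## BOLD forward model and GLMs

The forward model writes parcel signal = 100 + coupling ×
(HRF-convolved impulse train of mean-centered model values at trial
onsets) + optional confound leakage + white noise, with smooth AR(1)
pseudo-motion and noisy tissue-mean series as confounds. It makes no
claim to realistic scanner noise (no drift or physiological structure),
so passing recovery tests demonstrate correctness of the estimators,
not robustness to real artifacts.

The AM pathway per run: optional initial-frame removal (default 8 on
real data, 0 on synthetic runs which have no pre-steady-state frames)
and mean-100 normalization; OLS removal of the 21-column nuisance model
(6 motion + first differences, zero-padded + squares + WM/CSF/global);
AM regression of the residuals on the model series convolved with a
Gaussian HRF (peak delay 5 s, FWHM 5 s, support 16 s — the kernel
family's parameters are configuration, as no canonical values exist for
it); amplitudes are mean-centered per run so the regressor carries
modulation rather than mean task response. Onsets snap to the nearest
frame (TR 0.8 s). Run estimates combine by fixed effects
(inverse-variance weighting); the group map is a per-unit intercept
test of subject betas (optional centered covariates), t mapped to z
through matched tail probabilities and capped at ±40 to avoid overflow.
Note the two-step shortcut (residualize, then fit) equals the joint
model containing the confounds only when the AM regressor is
orthogonalized against them first; the difference is tested explicitly
and left visible — at realistic confound correlation it attenuates
betas uniformly without reordering them.

The trial-level pathway builds one regressor per trial — a boxcar from
the go-stimulus onset lasting the trial's RT, convolved with the
canonical double-gamma HRF on a TR/16 microtime grid — and estimates
all trial betas jointly (least-squares-all). Trials without an RT
(stops, omissions) get a duration read off the interpolated z series
mapped back to ms through the run's valid-trial moments, so every trial
has a column. Under-determined or ill-conditioned designs (condition
number > 1e8) fall back to a flagged ridge solve that never shrinks the
intercept. Per subject, Pearson correlations between go-trial betas and
each model series (the same series the AM pathway used, by default) are
summarized per parcel by a regression on intercept + centered age + sex;
Cohen's d = intercept / residual SD. With centered covariates this
equals the alternative t/√n reading exactly (the intercept column is
orthogonal to the covariates), so the two switch options coincide
whenever covariates are centered; no Fisher-z transform of r is applied
by default (switchable).

## Map comparison

Thresholding splits a z map into disjoint positive (> +thr) and
negative (< −thr) unit sets; no cluster-extent filter is applied before
Dice (2|A∩B|/(|A|+|B|), missing when both masks are empty). Network
coverage is the percent of each network's parcels inside a mask.

Map-to-map Pearson correlations are tested by permuting one map:
plain value shuffles by default (exact for autocorrelation-free
synthetic maps), or variogram-matching surrogates when the maps carry
spatial autocorrelation. The surrogate generator permutes the map,
smooths the permutation with Gaussian distance kernels over a grid of
bandwidths (distance quantiles 0.02–0.5 on the unit coordinates), and
for each bandwidth fits nonnegative scale and nugget coefficients so
the surrogate's binned semivariogram (20 distance-quantile bins up to
the 75th percentile, weights decaying over bins to privilege the
short-distance structure) matches the observed one; the best bandwidth
wins. Surrogates preserve the variogram approximately — in tests the
median relative variogram error is below 0.25 and below the shuffle
error on smooth maps — not the value multiset. P-values use the
two-sided add-one rule, p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm),
with n_perm defaulting to 10,000.

## Simulated group studies and problem sizes

`simulate_study` generates n subjects (default 20), couples each
subject's BOLD to their own smoothed z-score series with a +c/0/−c
pattern by network (+2 in DorsalAttn, −2 in Default by default, white
noise SD 1) on the packaged 333-parcel/13-network synthetic
parcellation, and runs both pathways blind to the truth. The
parcellation reuses the real atlas's network sizes but synthetic,
network-clustered centroids; it supports coverage/effect/null code
without any atlas download and makes no anatomical claim. Default study
sizes (20 subjects, 2 runs, 333 parcels, 3 HMM restarts) keep a full
study under ~10 s while leaving all recovery margins wide.

With group sizes this small the t→z map values saturate far below the
very large z values a population-scale study prints; comparisons
between models therefore use a display threshold scaled to the maps
(e.g. 90% of the median coupled-parcel z) rather than an absolute
cutoff.

## Known limitations

- The noise model is white plus optional linear confound leakage; no
  drift, physiology, or volumetric motion simulation.
- The race model uses a fixed (non-stochastic) SSRT.
- Group-level inference is fixed/OLS only; no random-effects variance
  components.
- Voxel-level data are supported as flattened matrices through the same
  operations; no volumetric registration, slice timing or spatial
  smoothing.
- The three-state extension of the HMM is out of scope.
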