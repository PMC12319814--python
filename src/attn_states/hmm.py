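"""Two-state Gaussian hidden Markov model for RT series.

Baum-Welch (EM) with the scaled forward-backward recursions, multiple
random restarts, and Viterbi decoding. The fitted model is canonically
relabeled so that state 1 is the longer-RT ("inattentive") state, making
the posterior P(state 1) positively related to RT across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMMFit", "fit_gaussian_hmm", "forward_backward", "viterbi"]

_TINY = 1e-300


@dataclass
class HMMFit:
    """Fitted Gaussian HMM parameters and per-trial inferences.

    state_prob is the forward-backward posterior P(longer-RT state) per
    trial; viterbi_path the hard most-likely-state sequence. ll_trace
    holds the log-likelihood after each EM iteration (nondecreasing).
    """

    means: np.ndarray
    variances: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    ll_trace: np.ndarray
    converged: bool
    state_prob: np.ndarray
    viterbi_path: np.ndarray
    relabeled: bool = False
    n_iter: int = 0


def _emission_probs(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(T, K) Gaussian densities, floored away from exact zero."""
    d = x[:, None] - means[None, :]
    b = np.exp(-0.5 * d * d / variances[None, :]) / np.sqrt(2.0 * np.pi * variances[None, :])
    return np.maximum(b, _TINY)


def forward_backward(x: np.ndarray, means: np.ndarray, variances: np.ndarray,
                     transmat: np.ndarray, startprob: np.ndarray):
    """Scaled forward-backward pass.

    Returns (log_likelihood, gamma, xi_sum) where gamma[t, k] is the
    posterior state probability and xi_sum[i, j] the expected transition
    counts summed over time.
    """
    b = _emission_probs(x, means, variances)
    T, K = b.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)

    alpha[0] = startprob * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ transmat) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]

    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transmat @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    # expected transition counts (scaled recursions make the c's cancel)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = transmat * np.outer(alpha[t], b[t + 1] * beta[t + 1]) / c[t + 1]
        xi_sum += xi

    return float(np.log(c).sum()), gamma, xi_sum


def viterbi(x: np.ndarray, means: np.ndarray, variances: np.ndarray,
            transmat: np.ndarray, startprob: np.ndarray) -> np.ndarray:
    """Most likely state path (log-space dynamic program)."""
    logb = np.log(_emission_probs(x, means, variances))
    logA = np.log(np.maximum(transmat, _TINY))
    T, K = logb.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=int)
    delta[0] = np.log(np.maximum(startprob, _TINY)) + logb[0]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + logA
        psi[t] = scores.argmax(axis=0)
        delta[t] = scores.max(axis=0) + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta[-1].argmax())
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _random_init(x: np.ndarray, n_states: int, rng: np.random.Generator):
    """Random means drawn from data quantiles; shared data variance;
    diagonally-dominant random transition matrix."""
    q = np.sort(rng.uniform(0.05, 0.95, size=n_states))
    means = np.quantile(x, q)
    if np.ptp(means) < 1e-6:  # degenerate quantile draw
        means = means + np.linspace(-0.1, 0.1, n_states) * max(x.std(), 1e-3)
    variances = np.full(n_states, max(x.var(), 1e-3))
    transmat = np.full((n_states, n_states), 0.2 / max(n_states - 1, 1))
    np.fill_diagonal(transmat, 0.8)
    transmat = transmat + rng.uniform(0, 0.05, size=transmat.shape)
    transmat /= transmat.sum(axis=1, keepdims=True)
    startprob = np.full(n_states, 1.0 / n_states)
    return means, variances, transmat, startprob


def fit_gaussian_hmm(
    values: np.ndarray,
    n_states: int = 2,
    n_restarts: int = 10,
    tol: float = 1e-4,
    max_iter: int = 500,
    seed: int | None = None,
    var_floor: float = 1e-4,
) -> HMMFit:
    """Fit by Baum-Welch, keeping the best of ``n_restarts`` random
    initializations by final log-likelihood.

    Convergence: |delta log-likelihood| < tol within max_iter iterations.
    Emission variances are floored at ``var_floor`` to stop single-point
    collapse. With max_iter = 0 the initialization itself is scored and
    returned (converged = False).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    if np.any(np.isnan(x)):
        raise ValueError("series must be complete (no NaNs)")
    if len(x) < 2 * n_states:
        raise ValueError("need at least 2 x n_states observations")
    rng = np.random.default_rng(seed)

    best: HMMFit | None = None
    for _ in range(max(1, n_restarts)):
        means, variances, transmat, startprob = _random_init(x, n_states, rng)
        ll_trace: list[float] = []
        converged = False
        ll_prev = -np.inf
        n_done = 0

        ll, gamma, xi_sum = forward_backward(x, means, variances, transmat, startprob)
        for it in range(max_iter):
            # M-step from current posteriors
            occ = gamma.sum(axis=0)
            means = (gamma * x[:, None]).sum(axis=0) / occ
            variances = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / occ
            variances = np.maximum(variances, var_floor)
            transmat = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), _TINY)
            startprob = gamma[0] / gamma[0].sum()
            # E-step / likelihood of the updated model
            ll, gamma, xi_sum = forward_backward(x, means, variances, transmat, startprob)
            ll_trace.append(ll)
            n_done = it + 1
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        if max_iter == 0:
            ll_trace = [ll]

        fit = HMMFit(means=means, variances=variances, transmat=transmat,
                     startprob=startprob, log_likelihood=ll,
                     ll_trace=np.asarray(ll_trace), converged=converged,
                     state_prob=gamma[:, -1].copy(), viterbi_path=np.empty(0, dtype=int),
                     n_iter=n_done)
        fit.state_prob = gamma  # keep full posterior until relabeling below
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit

    assert best is not None
    gamma = best.state_prob  # (T, K)
    order = np.argsort(best.means)
    relabeled = not np.array_equal(order, np.arange(n_states))
    best.means = best.means[order]
    best.variances = best.variances[order]
    best.transmat = best.transmat[np.ix_(order, order)]
    best.startprob = best.startprob[order]
    gamma = gamma[:, order]
    best.relabeled = relabeled
    best.state_prob = gamma[:, -1]  # P(longest-mean state)
    path = viterbi(x, best.means, best.variances, best.transmat, best.startprob)
    best.viterbi_path = path
    return best
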