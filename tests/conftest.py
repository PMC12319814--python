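import numpy as np
import pytest

from attn_states import AttentionGenParams, SSTDesign, simulate_subject
from attn_states.pipeline import compute_models, prepare_zseries


@pytest.fixture(scope="session")
def default_runs():
    """One subject under the default task design and generator."""
    return simulate_subject(SSTDesign(), AttentionGenParams(), seed=42)


@pytest.fixture(scope="session")
def zruns(default_runs):
    return prepare_zseries(default_runs)


@pytest.fixture(scope="session")
def subject_models(zruns):
    return compute_models(zruns, hmm_restarts=3, hmm_seed=0)


def smooth_oracle(onsets, values, fwhm_s):
    """Brute-force Gaussian kernel smoother over onset times."""
    sigma = fwhm_s / np.sqrt(8.0 * np.log(2.0))
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        w = np.array([np.exp(-((onsets[i] - onsets[j]) ** 2) / (2 * sigma ** 2))
                      for j in range(len(values))])
        out[i] = (w * values).sum() / w.sum()
    return out


def convolve_oracle(impulses, kernel):
    """Direct O(n*k) discrete convolution."""
    n = len(impulses)
    out = np.zeros(n)
    for i in range(n):
        for j in range(len(kernel)):
            if 0 <= i - j < n:
                out[i] += impulses[i - j] * kernel[j]
    return out


def sample_two_state_chain(rng, T, means, sds, stay):
    """Tiny reference sampler for a 2-state Gaussian-emission chain."""
    s = np.zeros(T, dtype=int)
    for t in range(1, T):
        s[t] = s[t - 1] if rng.random() < stay[s[t - 1]] else 1 - s[t - 1]
    x = np.where(s == 0, rng.normal(means[0], sds[0], T),
                 rng.normal(means[1], sds[1], T))
    return x, s
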