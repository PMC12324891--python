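"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's forward-backward code paths:
likelihoods come from explicit enumeration of all hidden-state paths,
and interval summaries from direct window scans.
"""

import itertools

import numpy as np
from scipy import special, stats


def _path_probability(path, p1, p2, init_uniform):
    if init_uniform:
        pr = 0.5
    else:
        a = 1.0 - p1[0]
        b = 1.0 - p2[0]
        pr = 0.5 if a + b == 0 else (b if path[0] == 0 else a) / (a + b)
    for t in range(1, len(path)):
        prev, cur = path[t - 1], path[t]
        if prev == 0:
            pr *= p1[t] if cur == 0 else 1.0 - p1[t]
        else:
            pr *= p2[t] if cur == 1 else 1.0 - p2[t]
    return pr


def enumerate_loglik(counts, eta, init_uniform=False):
    """Log-likelihood of one segment by summing over all 2^T paths."""
    T = len(counts)
    p1 = special.expit(eta[:, 0])
    p2 = special.expit(eta[:, 1])
    lam = np.exp(eta[:, 2:4])
    total = 0.0
    for path in itertools.product([0, 1], repeat=T):
        pr = _path_probability(path, p1, p2, init_uniform)
        for t, s in enumerate(path):
            pr *= stats.poisson.pmf(counts[t], lam[t, s])
        total += pr
    return np.log(total)


def enumerate_smoothing(counts, eta, init_uniform=False):
    """P(state_t = signalling | all observations) by path enumeration."""
    T = len(counts)
    p1 = special.expit(eta[:, 0])
    p2 = special.expit(eta[:, 1])
    lam = np.exp(eta[:, 2:4])
    joint = np.zeros(T)
    total = 0.0
    for path in itertools.product([0, 1], repeat=T):
        pr = _path_probability(path, p1, p2, init_uniform)
        for t, s in enumerate(path):
            pr *= stats.poisson.pmf(counts[t], lam[t, s])
        total += pr
        for t, s in enumerate(path):
            if s == 0:
                joint[t] += pr
    return joint / total


def hdi_by_window_scan(samples, mass):
    """Shortest window over sorted samples, by exhaustive scan."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    best = None
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if best is None or w < best[0] - 1e-300:
            if best is None or w < best[0]:
                best = (w, x[i], x[i + m - 1])
    return float(best[1]), float(best[2])
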