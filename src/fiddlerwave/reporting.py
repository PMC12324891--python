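"""Posterior summarisation and convergence diagnostics.

Shared by every fitting module: 89% highest-density intervals, posterior
modes, the probability of an effect in the opposite direction from the
bulk of the posterior mass, rank-normalised split R-hat and effective
sample size, plus tabular summaries and dot-interval plots.

Effect tables are reported on the link scale (log-odds for transition
and entry probabilities, log rate for wave rates); response-scale cell
predictions are produced by passing a per-draw ``transform``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

DEFAULT_HDI_MASS = 0.89


def hdi(samples, mass: float = DEFAULT_HDI_MASS) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally short windows break toward the earliest
    (lowest) window.  With very few samples the window covers the whole
    range; fewer than two samples cannot define an interval.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("hdi needs at least 2 samples")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the earliest minimum
    return float(x[i]), float(x[i + m - 1])


def prob_opposite(samples) -> tuple[float, str]:
    """Fraction of draws strictly on the minority side of zero.

    Returns ``(proportion, tag)`` where the tag is ``"Pr(b>0)"`` when
    most mass is negative and ``"Pr(b<0)"`` when most mass is positive;
    an exact tie reports 0.5 tagged ``"Pr(b>0)"`` by convention.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("prob_opposite needs at least 1 sample")
    pos = np.count_nonzero(x > 0) / x.size
    neg = np.count_nonzero(x < 0) / x.size
    if pos > neg:
        return neg, "Pr(b<0)"
    return pos, "Pr(b>0)"


def _split_chains(chains: np.ndarray) -> np.ndarray:
    c, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, half : 2 * half]])


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    r = stats.rankdata(chains, method="average").reshape(chains.shape)
    return special.ndtri((r - 3.0 / 8) / (chains.size - 2.0 * 3.0 / 8 + 1))


def _rhat_of(z: np.ndarray) -> float:
    """Plain between/within R-hat of already-split chains."""
    m, n = z.shape
    chain_means = z.mean(axis=1)
    b = n * np.var(chain_means, ddof=1)
    w = np.mean(np.var(z, axis=1, ddof=1))
    if w == 0:
        return np.nan
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def rhat(chains, method: str = "rank") -> float:
    """Split-chain potential scale reduction factor.

    ``method="rank"`` (default) is the rank-normalised version: the max
    of split R-hat on rank-normalised draws and on rank-normalised
    folded (|x - median|) draws.  ``method="classic"`` is the plain
    split R-hat.  Returns NaN (undefined diagnostic) when the pooled
    draws have zero variance.  Needs >= 2 chains of equal length >= 4.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("rhat needs >=2 chains of equal length >=4")
    if np.var(x) == 0:
        return np.nan
    split = _split_chains(x)
    if method == "classic":
        return _rhat_of(split)
    if method != "rank":
        raise ValueError(f"unknown rhat method {method!r}")
    bulk = _rhat_of(_rank_normalize(split))
    folded = np.abs(split - np.median(split))
    tail = _rhat_of(_rank_normalize(folded))
    return float(np.nanmax([bulk, tail]))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance at all lags via FFT (biased, 1/n)."""
    n = x.shape[-1]
    m = int(2 ** np.ceil(np.log2(2 * n)))
    xc = x - x.mean(axis=-1, keepdims=True)
    f = np.fft.rfft(xc, m, axis=-1)
    acov = np.fft.irfft(f * np.conjugate(f), m, axis=-1)[..., :n].real
    return acov / n


def ess(chains, method: str = "bulk") -> float:
    """Effective sample size with Geyer's initial monotone sequence.

    ``bulk`` rank-normalises the split chains first; ``mean`` works on
    the raw draws.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[1] < 4:
        raise ValueError("ess needs chains of length >=4")
    z = _split_chains(x)
    if method == "bulk":
        z = _rank_normalize(z)
    elif method != "mean":
        raise ValueError(f"unknown ess method {method!r}")
    m, n = z.shape
    if np.var(z) == 0:
        return np.nan
    acov = _autocovariance(z)
    mean_var = np.mean(acov[:, 0]) * n / (n - 1.0)
    var_plus = mean_var * (n - 1.0) / n
    if m > 1:
        var_plus += np.var(z.mean(axis=1), ddof=1)
    mean_acov = np.mean(acov, axis=0)

    rho_hat = np.zeros(n)
    rho_hat[0] = 1.0
    rho_even = 1.0
    rho_odd = 1.0 - (mean_var - mean_acov[1]) / var_plus
    rho_hat[1] = rho_odd
    # Geyer initial positive sequence
    t = 1
    while t < n - 3 and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - mean_acov[t + 1]) / var_plus
        rho_odd = 1.0 - (mean_var - mean_acov[t + 2]) / var_plus
        if (rho_even + rho_odd) >= 0:
            rho_hat[t + 1] = rho_even
            rho_hat[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho_hat[max_t + 1] = rho_even
    # Geyer initial monotone sequence
    t = 1
    while t <= max_t - 2:
        if rho_hat[t + 1] + rho_hat[t + 2] > rho_hat[t - 1] + rho_hat[t]:
            rho_hat[t + 1] = (rho_hat[t - 1] + rho_hat[t]) / 2.0
            rho_hat[t + 2] = rho_hat[t + 1]
        t += 2
    tau = -1.0 + 2.0 * np.sum(rho_hat[: max_t + 1]) + rho_hat[max_t + 1]
    tau = max(tau, 1.0 / np.log10(m * n)) if m * n > 10 else max(tau, 1e-3)
    return float(m * n / tau)


def mode_estimate(samples) -> float:
    """Posterior mode via Gaussian-KDE argmax on a 512-point grid."""
    x = np.asarray(samples, dtype=float).ravel()
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return np.nan
    if np.ptp(finite) == 0:
        return float(finite[0])
    try:
        kde = stats.gaussian_kde(finite)
    except np.linalg.LinAlgError:
        return float(np.median(finite))
    grid = np.linspace(finite.min(), finite.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize(
    draws: dict[str, np.ndarray],
    transform=None,
    mass: float = DEFAULT_HDI_MASS,
    rhat_method: str = "rank",
) -> pd.DataFrame:
    """One summary row per parameter (or transformed quantity).

    ``draws`` maps parameter name -> (n_chains, n_draws) array.
    ``transform`` is applied element-wise per draw before summarising
    (e.g. an inverse link); diagnostics (R-hat, ESS) are computed on the
    reporting scale.
    """
    rows = []
    for name, arr in draws.items():
        a = np.asarray(arr, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        if transform is not None:
            a = np.asarray(transform(a), dtype=float)
        flat = a.ravel()
        has_inf = not np.all(np.isfinite(flat))
        finite = flat[np.isfinite(flat)]
        lo, hi = hdi(finite if has_inf else flat, mass)
        p_opp, tag = prob_opposite(flat[~np.isnan(flat)])
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(flat)) if not has_inf else float(np.mean(finite)),
                "mode": mode_estimate(flat),
                "hdi_low": lo,
                "hdi_high": hi,
                "prob_opposite": p_opp,
                "direction": tag,
                "rhat": rhat(a, rhat_method) if a.shape[0] >= 2 and a.shape[1] >= 4 else np.nan,
                "ess": ess(a) if a.shape[1] >= 4 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def plot_state_probability(intervals: pd.DataFrame, ax=None):
    """Observed wave counts and decoded P(signalling) for one trial.

    ``intervals`` needs columns start_s, wave_count and p_signalling
    (NaN where the interval was not retained).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    t = intervals["start_s"].to_numpy() / 60.0
    ax.plot(t, intervals["p_signalling"], color="0.5", lw=1.2, label="P(signalling)")
    ax2 = ax.twinx()
    ax2.plot(t, intervals["wave_count"], ".", color="tab:orange", ms=4, label="waves / 5 s")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("P(signalling state)")
    ax2.set_ylabel("waves per 5 s")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_cell_intervals(summary: pd.DataFrame, ylabel: str = "", ax=None):
    """Dot-interval plot: posterior mode with HDI whiskers per cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    xs = np.arange(len(summary))
    ax.vlines(xs, summary["hdi_low"], summary["hdi_high"], color="0.3")
    ax.plot(xs, summary["mode"], "o", color="0.1")
    ax.set_xticks(xs)
    ax.set_xticklabels(summary["parameter"], rotation=30, ha="right")
    ax.set_ylabel(ylabel)
    return ax
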