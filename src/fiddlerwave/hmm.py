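"""Two-state hidden Markov model of claw-waving bouts.

Focal males alternate between a *signalling* state (actively displaying)
and a *non-signalling* state (above ground but not displaying); the
number of waves per 5-s interval is the observation from which the
state is inferred.  Four linear predictors carry the covariate effects,
each with fixed effects and a per-male random intercept:

1. logit P(stay in signalling state) from one interval to the next,
2. logit P(stay in non-signalling state),
3. log wave rate in the signalling state,
4. log wave rate in the non-signalling state.

The transition matrix is interval-specific (covariates such as female
presence vary per interval).  Each maximal run of retained intervals is
an independent sequence whose initial state distribution is the
stationary distribution of its first transition matrix.  Likelihoods
use the scaled forward algorithm; gradients come from forward-backward
expected sufficient statistics, so the model can be fitted with the
package's Hamiltonian Monte Carlo engine.

State labels are identified by constraining the signalling emission
intercept above the non-signalling one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import special

from . import design as dz
from ._hmc import SamplerResult, sample_hmc
from .events import Segment

SIGNALLING, NON_SIGNALLING = 0, 1
BLOCK_NAMES = ("stay_sig", "stay_non", "rate_sig", "rate_non")


class HmmError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data container


@dataclass
class HmmData:
    """Segmented observation stream ready for likelihood evaluation.

    Arrays are concatenated over segments; ``seg_starts``/``seg_lens``
    delimit them.  ``male_index`` maps each interval to a row of the
    random-intercept matrix.
    """

    counts: np.ndarray
    X: np.ndarray
    male_index: np.ndarray
    seg_starts: np.ndarray
    seg_lens: np.ndarray
    male_ids: tuple[str, ...]
    columns: tuple[str, ...]
    zscore_specs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.ascontiguousarray(self.counts, dtype=np.int64)
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        if np.any(self.counts < 0):
            raise HmmError("wave counts must be non-negative integers")
        if self.seg_starts.size == 0 or self.counts.size == 0:
            raise HmmError("no segments: empty observation stream")
        if np.any(self.seg_lens < 1):
            raise HmmError("segments must contain at least one interval")

    @property
    def n_males(self) -> int:
        return len(self.male_ids)

    @property
    def n_intervals(self) -> int:
        return int(self.counts.size)


def prepare_hmm_data(
    intervals: pd.DataFrame,
    metadata: list[dz.TrialMetadata],
    segments: list[Segment] | None = None,
    include_interaction: bool = False,
) -> HmmData:
    """Assemble the HMM dataset from binned interval records.

    ``intervals`` is the concatenated per-trial output of
    :func:`fiddlerwave.events.bin_events` +
    :func:`~fiddlerwave.events.apply_retention_rule`.  z-score specs
    are computed once from this dataset: trial-level covariates
    (temperature, carapace width, claw:carapace ratio) across trials,
    the tide-time covariate across retained interval midpoints.
    """
    from .events import segment_sequences

    meta_by_trial = {m.male_id: m for m in metadata}
    if segments is None:
        segments = segment_sequences(intervals)
    if not segments:
        raise HmmError("no retained segments in the dataset")

    trial_frame = dz.metadata_frame(metadata)
    specs = {}
    for name in ("temperature", "carapace_width", "claw_ratio"):
        _, specs[name] = dz.z_score(trial_frame[name].to_numpy())
    retained = intervals[intervals["retained"]]
    midpoints = [
        meta_by_trial[str(t)].tide_offset_min + (s + dz.INTERVAL_S / 2) / 60.0
        for t, s in zip(retained["trial_id"], retained["start_s"])
    ]
    _, specs["tide_time"] = dz.z_score(np.asarray(midpoints))

    by_trial = {str(t): grp.set_index("interval_index") for t, grp in intervals.groupby("trial_id")}
    male_ids = tuple(sorted({m.male_id for m in metadata}))
    male_pos = {m: i for i, m in enumerate(male_ids)}
    cols = dz.hmm_design_columns(include_interaction)

    rows, counts, midx, seg_starts, seg_lens = [], [], [], [], []
    for seg in segments:
        if seg.trial_id not in meta_by_trial:
            raise HmmError(f"no metadata for trial {seg.trial_id!r}")
        meta = meta_by_trial[seg.trial_id]
        grp = by_trial[seg.trial_id]
        seg_starts.append(len(counts))
        seg_lens.append(seg.length)
        for k in range(seg.start_index, seg.start_index + seg.length):
            rec = grp.loc[k]
            row = dz.hmm_design_row(
                meta,
                rec["wave_level"],
                float(rec["start_s"]),
                int(rec["n_females"]),
                int(rec["rival_present"]),
                specs,
                include_interaction,
            )
            rows.append([row[c] for c in cols])
            counts.append(int(rec["wave_count"]))
            midx.append(male_pos[meta.male_id])
    return HmmData(
        counts=np.asarray(counts),
        X=np.asarray(rows, dtype=float),
        male_index=np.asarray(midx, dtype=np.int64),
        seg_starts=np.asarray(seg_starts, dtype=np.int64),
        seg_lens=np.asarray(seg_lens, dtype=np.int64),
        male_ids=male_ids,
        columns=cols,
        zscore_specs=specs,
    )


# ---------------------------------------------------------------------------
# parameters


@dataclass
class HmmParameters:
    """Point parameters: four linear-predictor blocks + random intercepts.

    ``alpha`` are the four intercepts, ``beta`` the (4, p) fixed-effect
    coefficients in block order (stay-signalling logit, stay-non logit,
    log signalling rate, log non-signalling rate); ``u`` holds per-male
    random intercepts (n_males, 4); ``sigma`` their SDs.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    u: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.alpha.shape != (4,) or self.beta.shape[0] != 4:
            raise HmmError("parameters need 4 linear-predictor blocks")
        if np.any(self.sigma < 0):
            raise HmmError("random-intercept SDs must be non-negative")

    def linear_predictors(self, X: np.ndarray, male_index: np.ndarray) -> np.ndarray:
        """(N, 4) array of per-interval linear predictors."""
        eta = self.alpha[None, :] + X @ self.beta.T
        if self.u.size:
            eta = eta + self.u[male_index]
        if not np.all(np.isfinite(eta)):
            raise HmmError("non-finite linear predictor")
        return eta


def transition_matrix(params: HmmParameters, design_row, male_index: int = 0) -> np.ndarray:
    """Interval-specific 2x2 transition matrix (rows: from-state, sum to 1)."""
    x = np.asarray(design_row, dtype=float)[None, :]
    eta = params.linear_predictors(x, np.asarray([male_index]))[0]
    p_sig = special.expit(eta[0])
    p_non = special.expit(eta[1])
    return np.array([[p_sig, 1 - p_sig], [1 - p_non, p_non]])


def expected_bout_length(p_stay: float, width_s: float = dz.INTERVAL_S) -> float:
    """Mean bout duration implied by a stay probability.

    Dwell time in a state is geometric; counting the first interval the
    mean bout spans ``width_s / (1 - p_stay)`` seconds.
    """
    if not 0 <= p_stay < 1:
        raise HmmError("p_stay must lie in [0, 1); p_stay = 1 gives an infinite bout")
    return width_s / (1.0 - p_stay)


# ---------------------------------------------------------------------------
# forward-backward kernel


@njit(cache=True)
def _fb_kernel(B, p1, p2, seg_starts, seg_lens, init_uniform, want_grad):
    """Scaled forward(-backward) pass over all segments.

    ``B``: (N, 2) emission log-probabilities; ``p1``/``p2``: per-interval
    stay probabilities (transition *into* interval t uses index t; index
    seg_start parameterises the initial distribution).  Returns the
    total log-likelihood, the smoothed state probabilities ``gB`` (which
    equal dL/dB), and dL/dlogit(p1), dL/dlogit(p2).
    """
    N = B.shape[0]
    loglik = 0.0
    gB = np.zeros((N, 2))
    gp1 = np.zeros(N)
    gp2 = np.zeros(N)
    tiny = 1e-300

    for s in range(seg_starts.shape[0]):
        lo = seg_starts[s]
        T = seg_lens[s]
        e = np.empty((T, 2))
        for t in range(T):
            e[t, 0] = np.exp(B[lo + t, 0])
            e[t, 1] = np.exp(B[lo + t, 1])

        # initial distribution
        if init_uniform:
            pi0, pi1 = 0.5, 0.5
        else:
            a = 1.0 - p1[lo]
            b = 1.0 - p2[lo]
            tot = a + b
            if tot < tiny:
                pi0, pi1 = 0.5, 0.5
            else:
                pi0 = b / tot
                pi1 = a / tot

        alpha = np.empty((T, 2))
        c = np.empty(T)
        a0 = pi0 * e[0, 0]
        a1 = pi1 * e[0, 1]
        c[0] = a0 + a1
        if c[0] < tiny:
            c[0] = tiny
        alpha[0, 0] = a0 / c[0]
        alpha[0, 1] = a1 / c[0]
        for t in range(1, T):
            q1 = p1[lo + t]
            q2 = p2[lo + t]
            a0 = (alpha[t - 1, 0] * q1 + alpha[t - 1, 1] * (1.0 - q2)) * e[t, 0]
            a1 = (alpha[t - 1, 0] * (1.0 - q1) + alpha[t - 1, 1] * q2) * e[t, 1]
            c[t] = a0 + a1
            if c[t] < tiny:
                c[t] = tiny
            alpha[t, 0] = a0 / c[t]
            alpha[t, 1] = a1 / c[t]
        for t in range(T):
            loglik += np.log(c[t])

        if not want_grad:
            continue

        # backward pass (scaled) and expected statistics
        beta = np.empty((T, 2))
        beta[T - 1, 0] = 1.0
        beta[T - 1, 1] = 1.0
        for t in range(T - 2, -1, -1):
            q1 = p1[lo + t + 1]
            q2 = p2[lo + t + 1]
            b0n = e[t + 1, 0] * beta[t + 1, 0]
            b1n = e[t + 1, 1] * beta[t + 1, 1]
            beta[t, 0] = (q1 * b0n + (1.0 - q1) * b1n) / c[t + 1]
            beta[t, 1] = ((1.0 - q2) * b0n + q2 * b1n) / c[t + 1]
        for t in range(T):
            gB[lo + t, 0] = alpha[t, 0] * beta[t, 0]
            gB[lo + t, 1] = alpha[t, 1] * beta[t, 1]
        for t in range(1, T):
            q1 = p1[lo + t]
            q2 = p2[lo + t]
            b0 = e[t, 0] * beta[t, 0] / c[t]
            b1 = e[t, 1] * beta[t, 1] / c[t]
            xi00 = alpha[t - 1, 0] * q1 * b0
            xi01 = alpha[t - 1, 0] * (1.0 - q1) * b1
            xi10 = alpha[t - 1, 1] * (1.0 - q2) * b0
            xi11 = alpha[t - 1, 1] * q2 * b1
            gp1[lo + t] = xi00 * (1.0 - q1) - xi01 * q1
            gp2[lo + t] = xi11 * (1.0 - q2) - xi10 * q2

        # initial-distribution dependence on the first transition matrix
        if not init_uniform:
            a = 1.0 - p1[lo]
            b = 1.0 - p2[lo]
            tot = a + b
            if tot >= tiny:
                g0 = gB[lo, 0] / pi0 if pi0 > tiny else 0.0
                g1 = gB[lo, 1] / pi1 if pi1 > tiny else 0.0
                dL_da = (b / (tot * tot)) * (g1 - g0)
                dL_db = (a / (tot * tot)) * (g0 - g1)
                gp1[lo] += dL_da * (-p1[lo] * (1.0 - p1[lo]))
                gp2[lo] += dL_db * (-p2[lo] * (1.0 - p2[lo]))

    return loglik, gB, gp1, gp2


def _emission_terms(counts, eta_rate, emission: str, log_r: float | None):
    """Emission log-pmfs and their derivatives w.r.t. the log mean.

    Returns ``B`` (N,2), ``dB`` (N,2) = dB/dlog(rate), and for the
    negative binomial also dB/dlog(r) (N,2).
    """
    y = counts[:, None].astype(float)
    mu = np.exp(eta_rate)  # (N, 2)
    if emission == "poisson":
        B = y * eta_rate - mu - special.gammaln(y + 1.0)
        dB = y - mu
        return B, dB, None
    if emission == "negbin":
        r = np.exp(log_r)
        B = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * (np.log(r) - np.log(r + mu))
            + y * (eta_rate - np.log(r + mu))
        )
        dB = (y - mu) * r / (r + mu)
        dB_dlogr = r * (
            special.digamma(y + r)
            - special.digamma(r)
            + np.log(r)
            - np.log(r + mu)
            + (mu - y) / (r + mu)
        )
        return B, dB, dB_dlogr
    raise HmmError(f"unknown emission family {emission!r}")


def _loglik_terms(data: HmmData, eta: np.ndarray, emission: str, log_r, init: str, want_grad: bool):
    p1 = special.expit(eta[:, 0])
    p2 = special.expit(eta[:, 1])
    B, dB, dB_dlogr = _emission_terms(data.counts, eta[:, 2:4], emission, log_r)
    ll, gB, gp1, gp2 = _fb_kernel(
        B, p1, p2, data.seg_starts, data.seg_lens, init == "uniform", want_grad
    )
    if not want_grad:
        return ll, None, None
    g_eta = np.empty_like(eta)
    g_eta[:, 0] = gp1
    g_eta[:, 1] = gp2
    g_eta[:, 2] = gB[:, 0] * dB[:, 0]
    g_eta[:, 3] = gB[:, 1] * dB[:, 1]
    g_logr = float(np.sum(gB * dB_dlogr)) if dB_dlogr is not None else None
    return ll, g_eta, g_logr


def forward_loglik(
    data: HmmData,
    params: HmmParameters,
    emission: str = "poisson",
    log_r: float | None = None,
    init: str = "stationary",
) -> float:
    """Marginal log-likelihood via the scaled forward algorithm."""
    if data.n_intervals == 0:
        raise HmmError("empty observation stream")
    eta = params.linear_predictors(data.X, data.male_index)
    ll, _, _ = _loglik_terms(data, eta, emission, log_r, init, want_grad=False)
    return float(ll)


def decode_states(
    params_or_posterior,
    data: HmmData,
    emission: str = "poisson",
    init: str = "stationary",
    n_draws: int = 50,
) -> pd.DataFrame:
    """Forward-backward smoothing: P(signalling | segment observations).

    Accepts point :class:`HmmParameters` or a fitted
    :class:`HmmPosterior` (probabilities averaged over ``n_draws``
    thinned posterior draws).
    """
    if isinstance(params_or_posterior, HmmPosterior):
        post = params_or_posterior
        total = post.n_draws_total
        take = np.unique(np.linspace(0, total - 1, min(n_draws, total)).astype(int))
        gam = np.zeros(data.n_intervals)
        for i in take:
            gam += _decode_point(post.point_parameters(i), data, emission, post.log_r_draw(i), init)
        gam /= take.size
    else:
        gam = _decode_point(params_or_posterior, data, emission, None, init)
    return pd.DataFrame(
        {
            "segment": np.repeat(np.arange(data.seg_starts.size), data.seg_lens),
            "male_index": data.male_index,
            "wave_count": data.counts,
            "p_signalling": gam,
        }
    )


def _decode_point(params, data, emission, log_r, init):
    eta = params.linear_predictors(data.X, data.male_index)
    _, gB, _, _ = _fb_kernel(
        *_fb_inputs(data, eta, emission, log_r, init), True
    )
    total = gB.sum(axis=1)
    return gB[:, 0] / np.where(total > 0, total, 1.0)


def _fb_inputs(data, eta, emission, log_r, init):
    p1 = special.expit(eta[:, 0])
    p2 = special.expit(eta[:, 1])
    B, _, _ = _emission_terms(data.counts, eta[:, 2:4], emission, log_r)
    return B, p1, p2, data.seg_starts, data.seg_lens, init == "uniform"


# ---------------------------------------------------------------------------
# Bayesian fit


@dataclass(frozen=True)
class HmmPriors:
    """Weakly informative regularising priors on the link scale."""

    coef_scale: float = 1.5
    sigma_scale: float = 1.0
    logr_scale: float = 2.5


@dataclass
class HmmPosterior:
    """Posterior draws of all HMM parameters plus sampler metadata."""

    draws: dict[str, np.ndarray]
    random_effect_draws: np.ndarray  # (chains, draws, n_males, 4), actual u
    columns: tuple[str, ...]
    male_ids: tuple[str, ...]
    emission: str
    init: str
    sampler: SamplerResult
    zscore_specs: dict = field(default_factory=dict)

    @property
    def n_draws_total(self) -> int:
        any_param = next(iter(self.draws.values()))
        return int(any_param.size)

    def _flat(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).ravel()

    def log_r_draw(self, i: int):
        return self._flat("log_r")[i] if "log_r" in self.draws else None

    def point_parameters(self, i: int) -> HmmParameters:
        alpha = np.array([self._flat(f"{b}_intercept")[i] for b in BLOCK_NAMES])
        beta = np.array(
            [[self._flat(f"{b}_{c}")[i] for c in self.columns] for b in BLOCK_NAMES]
        )
        sigma = np.array([self._flat(f"sigma_{b}")[i] for b in BLOCK_NAMES])
        nc, nd = self.random_effect_draws.shape[:2]
        u = self.random_effect_draws.reshape(nc * nd, *self.random_effect_draws.shape[2:])[i]
        return HmmParameters(alpha, beta, sigma, u, self.columns)

    def mean_parameters(self) -> HmmParameters:
        alpha = np.array([self._flat(f"{b}_intercept").mean() for b in BLOCK_NAMES])
        beta = np.array(
            [[self._flat(f"{b}_{c}").mean() for c in self.columns] for b in BLOCK_NAMES]
        )
        sigma = np.array([self._flat(f"sigma_{b}").mean() for b in BLOCK_NAMES])
        u = self.random_effect_draws.mean(axis=(0, 1))
        return HmmParameters(alpha, beta, sigma, u, self.columns)

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten fixed-effect and SD draws to a (chain, draw) table."""
        cols = {}
        for name, arr in self.draws.items():
            a = np.asarray(arr)
            cols[name] = a.ravel()
        nc, nd = next(iter(self.draws.values())).shape
        out = pd.DataFrame(cols)
        out.insert(0, "chain", np.repeat(np.arange(nc), nd))
        out.insert(1, "draw", np.tile(np.arange(nd), nc))
        return out


def fit_hmm(
    data: HmmData,
    priors: HmmPriors | None = None,
    *,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    emission: str = "poisson",
    init: str = "stationary",
    target_accept: float = 0.85,
    max_leapfrog: int = 48,
    rhat_threshold: float = 1.01,
) -> HmmPosterior:
    """Fit the covariate HMM by Hamiltonian Monte Carlo.

    Random intercepts use the non-centred parameterisation
    ``u = sigma * z`` with ``z ~ N(0, 1)`` and half-normal priors on
    the SDs.  The signalling emission intercept is constrained above
    the non-signalling one (label identification).  Runs with the same
    seed and configuration return identical draws.  Non-convergence
    (max rank-normalised split R-hat above ``rhat_threshold``) is
    flagged in the returned sampler diagnostics via a warning, never
    silently ignored.
    """
    from .reporting import rhat as _rhat

    priors = priors or HmmPriors()
    p = len(data.columns)
    M = data.n_males
    negbin = emission == "negbin"
    # layout: alpha(4) | beta(4*p) | log_sigma(4) | z(M*4) | [log_r]
    dim = 4 + 4 * p + 4 + 4 * M + (1 if negbin else 0)
    i_alpha = slice(0, 4)
    i_beta = slice(4, 4 + 4 * p)
    i_lsig = slice(4 + 4 * p, 8 + 4 * p)
    i_z = slice(8 + 4 * p, 8 + 4 * p + 4 * M)

    X = data.X
    midx = data.male_index
    cs, ss = priors.coef_scale, priors.sigma_scale

    def logp_grad(v: np.ndarray):
        alpha = v[i_alpha]
        beta = v[i_beta].reshape(4, p)
        lsig = v[i_lsig]
        z = v[i_z].reshape(M, 4)
        log_r = v[-1] if negbin else None
        if alpha[2] <= alpha[3]:  # label-identification constraint
            return -np.inf, np.zeros_like(v)
        sigma = np.exp(lsig)
        u = sigma[None, :] * z
        eta = alpha[None, :] + X @ beta.T + u[midx]
        if not np.all(np.isfinite(eta)) or np.any(eta[:, 2:4] > 30):
            return -np.inf, np.zeros_like(v)  # overflow region: reject
        ll, g_eta, g_logr = _loglik_terms(data, eta, emission, log_r, init, True)

        grad = np.empty_like(v)
        grad[i_alpha] = g_eta.sum(axis=0) - alpha / cs**2
        gb = X.T @ g_eta  # (p, 4)
        grad[i_beta] = (gb.T - beta / cs**2).ravel()
        g_u = np.zeros((M, 4))
        for k in range(4):
            g_u[:, k] = np.bincount(midx, weights=g_eta[:, k], minlength=M)
        grad[i_z] = (g_u * sigma[None, :] - z).ravel()
        grad[i_lsig] = (g_u * z).sum(axis=0) * sigma - (sigma / ss) ** 2 + 1.0
        lp = (
            ll
            - 0.5 * np.sum((alpha / cs) ** 2)
            - 0.5 * np.sum((beta / cs) ** 2)
            - 0.5 * np.sum((sigma / ss) ** 2)
            + np.sum(lsig)
            - 0.5 * np.sum(z**2)
        )
        if negbin:
            lp += -0.5 * (log_r / priors.logr_scale) ** 2
            grad[-1] = g_logr - log_r / priors.logr_scale**2
        return lp, grad

    x0 = _initial_point(data, p, M, negbin)
    res = sample_hmc(
        logp_grad,
        x0,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        seed=seed,
        target_accept=target_accept,
        max_leapfrog=max_leapfrog,
        jitter=0.02,
    )

    d = res.draws  # (chains, draws, dim)
    draws: dict[str, np.ndarray] = {}
    for k, b in enumerate(BLOCK_NAMES):
        draws[f"{b}_intercept"] = d[:, :, k]
        for j, c in enumerate(data.columns):
            draws[f"{b}_{c}"] = d[:, :, 4 + k * p + j]
        draws[f"sigma_{b}"] = np.exp(d[:, :, 4 + 4 * p + k])
    if negbin:
        draws["log_r"] = d[:, :, -1]

    lsig_draws = d[:, :, i_lsig]
    z_draws = d[:, :, i_z].reshape(d.shape[0], d.shape[1], M, 4)
    u_draws = np.exp(lsig_draws)[:, :, None, :] * z_draws

    post = HmmPosterior(
        draws=draws,
        random_effect_draws=u_draws,
        columns=data.columns,
        male_ids=data.male_ids,
        emission=emission,
        init=init,
        sampler=res,
        zscore_specs=data.zscore_specs,
    )
    worst = max(
        _rhat(np.asarray(arr))
        for name, arr in draws.items()
        if np.asarray(arr).shape[0] >= 2 and np.asarray(arr).shape[1] >= 4
    ) if n_chains >= 2 and n_draws >= 4 else np.nan
    if np.isfinite(worst) and worst > rhat_threshold:
        warnings.warn(
            f"HMM fit may not have converged: max R-hat {worst:.3f} > {rhat_threshold}"
        )
    return post


def _initial_point(data: HmmData, p: int, M: int, negbin: bool) -> np.ndarray:
    """Moment-based starting point: split counts into active/quiet rates."""
    y = data.counts
    pos = y[y > 0]
    lam_hi = float(pos.mean()) if pos.size else 1.0
    lam_lo = max(1e-3, 0.05 * float(y.mean()) + 1e-3)
    lam_lo = min(lam_lo, 0.5 * lam_hi)
    dim = 4 + 4 * p + 4 + 4 * M + (1 if negbin else 0)
    x0 = np.zeros(dim)
    x0[0] = 1.0  # stay-signalling logit
    x0[1] = 2.0  # stay-non-signalling logit
    x0[2] = np.log(lam_hi)
    x0[3] = np.log(lam_lo)
    x0[4 + 4 * p : 8 + 4 * p] = np.log(0.3)
    if negbin:
        x0[-1] = np.log(10.0)
    return x0


# ---------------------------------------------------------------------------
# posterior predictions


def condition_grid(columns, claw_levels=("small",)) -> dict[str, np.ndarray]:
    """Design rows for the wave-speed (x claw) prediction grid.

    Continuous covariates sit at 0 (the z-score mean), context counts
    at 0, random intercepts at 0 — the reference male.
    """
    grid = {}
    for claw in claw_levels:
        for level in dz.WAVE_LEVELS:
            row = np.zeros(len(columns))
            for j, c in enumerate(columns):
                if c == "slow_wave":
                    row[j] = float(level == "slow")
                elif c == "fast_wave":
                    row[j] = float(level == "fast")
                elif c == "large_claw":
                    row[j] = float(claw == "large")
                elif c == "slow_x_large":
                    row[j] = float(level == "slow" and claw == "large")
                elif c == "fast_x_large":
                    row[j] = float(level == "fast" and claw == "large")
            name = level if len(claw_levels) == 1 else f"{level}_{claw}"
            grid[name] = row
    return grid


def predict_bout_lengths(
    posterior: HmmPosterior,
    grid: dict[str, np.ndarray] | None = None,
    width_s: float = dz.INTERVAL_S,
) -> pd.DataFrame:
    """Posterior summaries of expected signalling-bout length per condition.

    Per draw the stay-signalling probability at each grid cell is pushed
    through :func:`expected_bout_length`; draws at p_stay = 1 propagate
    as +inf with a warning and the HDI is taken over finite order
    statistics.
    """
    from .reporting import summarize

    grid = grid or condition_grid(posterior.columns)
    a0 = posterior.draws["stay_sig_intercept"]
    betas = np.stack(
        [posterior.draws[f"stay_sig_{c}"] for c in posterior.columns], axis=-1
    )
    out = {}
    for name, x in grid.items():
        logit = a0 + betas @ x
        p_stay = special.expit(logit)
        with np.errstate(divide="ignore"):
            out[name] = np.where(p_stay < 1.0, width_s / (1.0 - p_stay), np.inf)
        if np.any(~np.isfinite(out[name])):
            warnings.warn(f"bout-length draws at p_stay=1 in cell {name!r}: reported as +inf")
    return summarize(out)
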