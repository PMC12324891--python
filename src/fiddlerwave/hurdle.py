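"""Bernoulli-Beta hurdle model of burrow use.

For each 5-min wave-speed condition the focal male either never enters
his burrow, or enters and spends some fraction of the condition inside.
The hurdle model therefore has two parts sharing one design: a
Bernoulli part for whether he entered at all (logit link) and,
conditional on entry, a Beta part for the occupancy proportion
parameterised by mean (logit link) and precision phi.  Both parts carry
the experimental treatments (wave speed x robot claw size, presentation
order) and the standardised trial covariates, with a per-male random
intercept in each part.

Occupancy proportions sitting on the closed boundary (a male in his
burrow for a full condition) are nudged inside the open unit interval
with the usual smoothing transform ``(y (n-1) + 0.5) / n`` before
fitting, since the Beta support is open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import design as dz
from ._hmc import SamplerResult, sample_hmc


class HurdleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data


@dataclass
class HurdleData:
    """Per-condition burrow-use records with dummy-coded design rows."""

    X: np.ndarray
    entered: np.ndarray
    proportion: np.ndarray  # NaN where entered is False
    male_index: np.ndarray
    male_ids: tuple[str, ...]
    columns: tuple[str, ...]
    zscore_specs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.entered = np.asarray(self.entered, dtype=bool)
        self.proportion = np.asarray(self.proportion, dtype=float)
        occ = self.proportion[self.entered]
        if np.any(np.isnan(occ)):
            raise HurdleError("entered records must carry a proportion")
        if np.any((occ <= 0) | (occ > 1)):
            raise HurdleError("occupancy proportions must lie in (0, 1]")

    @property
    def n_males(self) -> int:
        return len(self.male_ids)

    def smoothed_proportion(self) -> np.ndarray:
        """Boundary-adjusted occupancy proportions on the open interval.

        Values equal to 1 (and, defensively, 0) are pulled inside via
        ``(y (n-1) + 0.5) / n`` with n the number of occupancy
        observations; interior values are untouched.
        """
        y = self.proportion.copy()
        occ = self.entered
        n = int(occ.sum())
        if n == 0:
            return y
        boundary = occ & ((y >= 1.0) | (y <= 0.0))
        y[boundary] = (y[boundary] * (n - 1) + 0.5) / n
        return y


def prepare_hurdle_data(
    burrow_records: pd.DataFrame, metadata: list[dz.TrialMetadata]
) -> HurdleData:
    """Assemble the hurdle dataset from per-condition burrow-use records.

    ``burrow_records`` is the concatenated output of
    :func:`fiddlerwave.events.summarize_burrow_use`; one row per
    condition per trial (the second no-wave condition contributes a
    second no-wave record).  z-score specs are computed across trials.
    """
    meta_by_trial = {m.male_id: m for m in metadata}
    specs = dz.compute_zscore_specs(dz.metadata_frame(metadata))
    male_ids = tuple(sorted({m.male_id for m in metadata}))
    male_pos = {m: i for i, m in enumerate(male_ids)}

    rows, entered, prop, midx = [], [], [], []
    for rec in burrow_records.itertuples():
        trial = str(rec.trial_id)
        if trial not in meta_by_trial:
            raise HurdleError(f"no metadata for trial {trial!r}")
        meta = meta_by_trial[trial]
        row = dz.hurdle_design_row(meta, rec.wave_level, specs)
        rows.append([row[c] for c in dz.HURDLE_COLUMNS])
        entered.append(bool(rec.entered))
        prop.append(float(rec.proportion_in_burrow) if rec.entered else np.nan)
        midx.append(male_pos[meta.male_id])
    return HurdleData(
        X=np.asarray(rows, dtype=float),
        entered=np.asarray(entered),
        proportion=np.asarray(prop),
        male_index=np.asarray(midx, dtype=np.int64),
        male_ids=male_ids,
        columns=dz.HURDLE_COLUMNS,
        zscore_specs=specs,
    )


# ---------------------------------------------------------------------------
# parameters & likelihood


@dataclass
class HurdleParameters:
    """Point parameters of the two-part model.

    ``beta_entry``/``beta_occ`` are fixed-effect coefficient vectors on
    the entry logit and the occupancy-mean logit; ``phi`` is the Beta
    precision; ``u_entry``/``u_occ`` hold per-male random intercepts.
    """

    intercept_entry: float
    beta_entry: np.ndarray
    intercept_occ: float
    beta_occ: np.ndarray
    phi: float
    sigma_entry: float = 0.0
    sigma_occ: float = 0.0
    u_entry: np.ndarray = field(default_factory=lambda: np.zeros(0))
    u_occ: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.beta_entry = np.asarray(self.beta_entry, dtype=float)
        self.beta_occ = np.asarray(self.beta_occ, dtype=float)
        self.u_entry = np.asarray(self.u_entry, dtype=float)
        self.u_occ = np.asarray(self.u_occ, dtype=float)
        if self.phi <= 0:
            raise HurdleError("Beta precision phi must be positive")
        if self.sigma_entry < 0 or self.sigma_occ < 0:
            raise HurdleError("random-intercept SDs must be non-negative")

    def entry_logit(self, X: np.ndarray, male_index: np.ndarray) -> np.ndarray:
        eta = self.intercept_entry + X @ self.beta_entry
        if self.u_entry.size:
            eta = eta + self.u_entry[male_index]
        return eta

    def occupancy_logit(self, X: np.ndarray, male_index: np.ndarray) -> np.ndarray:
        eta = self.intercept_occ + X @ self.beta_occ
        if self.u_occ.size:
            eta = eta + self.u_occ[male_index]
        return eta


def _beta_logpdf(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def hurdle_loglik(data: HurdleData, params: HurdleParameters) -> float:
    """Total log-likelihood: Bernoulli entry + Beta occupancy given entry.

    The two parts are independent given covariates, so the total
    decomposes into separately-fittable entry and occupancy sums.
    """
    y = data.smoothed_proportion()
    occ = data.entered
    if np.any((y[occ] <= 0) | (y[occ] >= 1)):
        raise HurdleError("occupancy proportions outside (0,1) after adjustment")
    eta_e = params.entry_logit(data.X, data.male_index)
    ll = float(np.sum(eta_e * occ - np.logaddexp(0.0, eta_e)))
    mu = special.expit(params.occupancy_logit(data.X, data.male_index)[occ])
    ll += float(np.sum(_beta_logpdf(y[occ], mu, params.phi)))
    return ll


# ---------------------------------------------------------------------------
# Bayesian fit


@dataclass(frozen=True)
class HurdlePriors:
    coef_scale: float = 1.5
    sigma_scale: float = 1.0
    logphi_scale: float = 2.5


@dataclass
class HurdlePosterior:
    """Posterior draws of all hurdle parameters plus sampler metadata."""

    draws: dict[str, np.ndarray]
    random_effect_draws: dict[str, np.ndarray]  # (chains, draws, n_males) per part
    columns: tuple[str, ...]
    male_ids: tuple[str, ...]
    sampler: SamplerResult
    zscore_specs: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {name: np.asarray(a).ravel() for name, a in self.draws.items()}
        nc, nd = next(iter(self.draws.values())).shape
        out = pd.DataFrame(cols)
        out.insert(0, "chain", np.repeat(np.arange(nc), nd))
        out.insert(1, "draw", np.tile(np.arange(nd), nc))
        return out


def fit_hurdle(
    data: HurdleData,
    priors: HurdlePriors | None = None,
    *,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    target_accept: float = 0.85,
    max_leapfrog: int = 24,
    rhat_threshold: float = 1.01,
) -> HurdlePosterior:
    """Fit the hurdle model by Hamiltonian Monte Carlo.

    Empty treatment cells leave the corresponding contrasts identified
    only through the prior; this is flagged with a warning rather than
    an error.  Same seed and configuration -> identical draws.
    """
    from .reporting import rhat as _rhat

    priors = priors or HurdlePriors()
    _warn_on_empty_cells(data)
    p = len(data.columns)
    M = data.n_males
    X = data.X
    midx = data.male_index
    occ = data.entered
    y = data.smoothed_proportion()
    if np.any((y[occ] <= 0) | (y[occ] >= 1)):
        raise HurdleError("occupancy proportions outside (0,1) after adjustment")
    y_occ = y[occ]
    X_occ = X[occ]
    midx_occ = midx[occ]
    logy = np.log(y_occ)
    log1my = np.log1p(-y_occ)
    ent = occ.astype(float)
    cs, ss = priors.coef_scale, priors.sigma_scale

    # layout: b_e(1+p) | b_o(1+p) | log_phi | log_sig_e | log_sig_o | z_e(M) | z_o(M)
    i_be = slice(0, 1 + p)
    i_bo = slice(1 + p, 2 + 2 * p)
    i_phi = 2 + 2 * p
    i_lse = 3 + 2 * p
    i_lso = 4 + 2 * p
    i_ze = slice(5 + 2 * p, 5 + 2 * p + M)
    i_zo = slice(5 + 2 * p + M, 5 + 2 * p + 2 * M)
    dim = 5 + 2 * p + 2 * M

    X1 = np.hstack([np.ones((X.shape[0], 1)), X])
    X1_occ = np.hstack([np.ones((X_occ.shape[0], 1)), X_occ])

    def logp_grad(v: np.ndarray):
        b_e, b_o = v[i_be], v[i_bo]
        log_phi, lse, lso = v[i_phi], v[i_lse], v[i_lso]
        z_e, z_o = v[i_ze], v[i_zo]
        if log_phi > 30 or lse > 30 or lso > 30:
            return -np.inf, np.zeros(dim)  # overflow region: reject
        phi = np.exp(log_phi)
        sig_e, sig_o = np.exp(lse), np.exp(lso)

        eta_e = X1 @ b_e + sig_e * z_e[midx]
        pe = special.expit(eta_e)
        ll = np.sum(eta_e * ent - np.logaddexp(0.0, eta_e))
        g_eta_e = ent - pe

        eta_o = X1_occ @ b_o + sig_o * z_o[midx_occ]
        mu = special.expit(eta_o)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll += np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * logy
            + (b - 1.0) * log1my
        )
        dmu = phi * (-special.digamma(a) + special.digamma(b) + logy - log1my)
        g_eta_o = dmu * mu * (1.0 - mu)
        g_logphi = phi * np.sum(
            special.digamma(phi)
            - mu * special.digamma(a)
            - (1.0 - mu) * special.digamma(b)
            + mu * logy
            + (1.0 - mu) * log1my
        )

        grad = np.empty(dim)
        grad[i_be] = X1.T @ g_eta_e - b_e / cs**2
        grad[i_bo] = X1_occ.T @ g_eta_o - b_o / cs**2
        gu_e = np.bincount(midx, weights=g_eta_e, minlength=M)
        gu_o = np.bincount(midx_occ, weights=g_eta_o, minlength=M)
        grad[i_ze] = gu_e * sig_e - z_e
        grad[i_zo] = gu_o * sig_o - z_o
        grad[i_lse] = np.sum(gu_e * z_e) * sig_e - (sig_e / ss) ** 2 + 1.0
        grad[i_lso] = np.sum(gu_o * z_o) * sig_o - (sig_o / ss) ** 2 + 1.0
        grad[i_phi] = g_logphi - log_phi / priors.logphi_scale**2

        lp = (
            ll
            - 0.5 * np.sum((b_e / cs) ** 2)
            - 0.5 * np.sum((b_o / cs) ** 2)
            - 0.5 * (log_phi / priors.logphi_scale) ** 2
            - 0.5 * (sig_e / ss) ** 2
            + lse
            - 0.5 * (sig_o / ss) ** 2
            + lso
            - 0.5 * np.sum(z_e**2)
            - 0.5 * np.sum(z_o**2)
        )
        return lp, grad

    x0 = np.zeros(dim)
    x0[0] = special.logit(np.clip(ent.mean(), 0.05, 0.95))
    x0[1 + p] = special.logit(np.clip(y_occ.mean() if y_occ.size else 0.3, 0.05, 0.95))
    x0[i_phi] = np.log(5.0)
    x0[i_lse] = x0[i_lso] = np.log(0.3)
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

    d = res.draws
    draws: dict[str, np.ndarray] = {"entry_intercept": d[:, :, 0]}
    for j, c in enumerate(data.columns):
        draws[f"entry_{c}"] = d[:, :, 1 + j]
    draws["occ_intercept"] = d[:, :, 1 + p]
    for j, c in enumerate(data.columns):
        draws[f"occ_{c}"] = d[:, :, 2 + p + j]
    draws["phi"] = np.exp(d[:, :, i_phi])
    draws["sigma_entry"] = np.exp(d[:, :, i_lse])
    draws["sigma_occ"] = np.exp(d[:, :, i_lso])
    re_draws = {
        "entry": np.exp(d[:, :, i_lse])[:, :, None] * d[:, :, i_ze],
        "occ": np.exp(d[:, :, i_lso])[:, :, None] * d[:, :, i_zo],
    }
    post = HurdlePosterior(
        draws=draws,
        random_effect_draws=re_draws,
        columns=data.columns,
        male_ids=data.male_ids,
        sampler=res,
        zscore_specs=data.zscore_specs,
    )
    if n_chains >= 2 and n_draws >= 4:
        worst = max(_rhat(np.asarray(a)) for a in draws.values())
        if np.isfinite(worst) and worst > rhat_threshold:
            warnings.warn(
                f"hurdle fit may not have converged: max R-hat {worst:.3f} > {rhat_threshold}"
            )
    return post


def _warn_on_empty_cells(data: HurdleData) -> None:
    slow = data.X[:, data.columns.index("slow_wave")]
    fast = data.X[:, data.columns.index("fast_wave")]
    large = data.X[:, data.columns.index("large_claw")]
    for level, sel in (("no_wave", (slow == 0) & (fast == 0)), ("slow", slow == 1), ("fast", fast == 1)):
        for claw, csel in (("small", large == 0), ("large", large == 1)):
            if not np.any(sel & csel):
                warnings.warn(
                    f"empty treatment cell {level} x {claw}: its contrast is prior-identified"
                )


# ---------------------------------------------------------------------------
# posterior predictions


def predict_cells(
    posterior: HurdlePosterior, grid: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Cell-wise posterior predictions on the response scale (Fig-3 style).

    For each wave-speed x claw-size cell (continuous covariates at 0,
    random intercepts at 0) every posterior draw's linear predictors
    are pushed through the inverse links, giving draws of P(enter) and
    of the expected occupancy proportion; each is summarised by its
    posterior mode and 89% HDI.  Cell quantities are linear
    combinations of the dummy-coded draws, not separate parameters.
    """
    from .hmm import condition_grid
    from .reporting import summarize

    grid = grid or condition_grid(posterior.columns, claw_levels=("small", "large"))
    b_entry = np.stack([posterior.draws[f"entry_{c}"] for c in posterior.columns], axis=-1)
    b_occ = np.stack([posterior.draws[f"occ_{c}"] for c in posterior.columns], axis=-1)
    out = {}
    for name, x in grid.items():
        out[f"p_enter[{name}]"] = special.expit(posterior.draws["entry_intercept"] + b_entry @ x)
        out[f"occupancy[{name}]"] = special.expit(posterior.draws["occ_intercept"] + b_occ @ x)
    summary = summarize(out)
    summary["cell"] = [n.split("[")[1][:-1] for n in summary["parameter"]]
    summary["part"] = [n.split("[")[0] for n in summary["parameter"]]
    return summary
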