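"""Bayesian inter-rater reliability (intra-class correlation).

A second coder independently scores a subset of trials on aggregate
measures (total waves, time not waving, time in burrow).  Agreement is
quantified by the one-way random-effects ICC: with ratings
``y_ij = mu + a_i + e_ij`` (unit i, rater j), ``a_i ~ N(0, sigma_u^2)``
and ``e_ij ~ N(0, sigma_r^2)``,

    ICC = sigma_u^2 / (sigma_u^2 + sigma_r^2),

the between-unit share of total variance.  Counts are treated as
continuous, consistent with the classical ICC.  Ratings are
standardised internally (ICC is invariant to common affine rescaling
of both raters' values), with half-normal priors on both SDs on the
standardised scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hmc import SamplerResult, sample_hmc

#: conventional reliability labels: below .5 poor, .5-.75 moderate,
#: .75-.9 good, above .9 excellent
DEFAULT_RELIABILITY_THRESHOLDS = (0.5, 0.75, 0.9)


class IccError(ValueError):
    pass


@dataclass
class PairedRatings:
    """Dual-coded values of one measure: one row per unit (trial)."""

    measure: str
    unit_ids: tuple[str, ...]
    rater1: np.ndarray
    rater2: np.ndarray

    def __post_init__(self):
        self.rater1 = np.asarray(self.rater1, dtype=float)
        self.rater2 = np.asarray(self.rater2, dtype=float)
        if self.rater1.shape != self.rater2.shape or self.rater1.ndim != 1:
            raise IccError("raters must supply one value each per unit")
        if self.rater1.size < 3:
            raise IccError("ICC needs at least 3 dual-coded units")
        if not (np.all(np.isfinite(self.rater1)) and np.all(np.isfinite(self.rater2))):
            raise IccError("ratings must be finite (both raters present per unit)")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, measure: str = "") -> "PairedRatings":
        for col in ("unit_id", "rater1", "rater2"):
            if col not in frame.columns:
                raise IccError(f"ratings table missing column {col!r}")
        return cls(
            measure=measure or str(frame.get("measure", pd.Series(["measure"])).iloc[0]),
            unit_ids=tuple(str(u) for u in frame["unit_id"]),
            rater1=frame["rater1"].to_numpy(dtype=float),
            rater2=frame["rater2"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class IccPriors:
    mu_scale: float = 2.0
    sigma_scale: float = 1.0


@dataclass
class IccPosterior:
    """Draws of the ICC and both variance components (original units)."""

    draws: dict[str, np.ndarray]
    measure: str
    sampler: SamplerResult

    def summary(self, thresholds=DEFAULT_RELIABILITY_THRESHOLDS) -> pd.DataFrame:
        from .reporting import summarize

        out = summarize(self.draws)
        icc_mean = float(np.mean(self.draws["icc"]))
        out["measure"] = self.measure
        out.loc[out["parameter"] == "icc", "reliability"] = reliability_label(
            icc_mean, thresholds
        )
        return out


def reliability_label(icc_value: float, thresholds=DEFAULT_RELIABILITY_THRESHOLDS) -> str:
    lo, mid, hi = thresholds
    if icc_value < lo:
        return "poor"
    if icc_value < mid:
        return "moderate"
    if icc_value < hi:
        return "good"
    return "excellent"


def fit_icc(
    ratings: PairedRatings,
    priors: IccPriors | None = None,
    *,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    target_accept: float = 0.9,
    max_leapfrog: int = 24,
    rhat_threshold: float = 1.01,
) -> IccPosterior:
    """Fit the one-way random-effects ICC model by HMC.

    Unit effects use the non-centred parameterisation.  Every ICC draw
    lies in [0, 1] by construction.
    """
    from .reporting import rhat as _rhat

    priors = priors or IccPriors()
    y = np.stack([ratings.rater1, ratings.rater2], axis=1)  # (n, 2)
    n = y.shape[0]
    scale = float(np.std(y))
    if scale == 0:
        raise IccError("all ratings identical: variance components undefined")
    center = float(np.mean(y))
    w = (y - center) / scale

    ms, ss = priors.mu_scale, priors.sigma_scale
    # layout: mu | log sigma_u | log sigma_r | z(n)
    dim = 3 + n

    def logp_grad(v: np.ndarray):
        mu, lsu, lsr = v[0], v[1], v[2]
        z = v[3:]
        su, sr = np.exp(lsu), np.exp(lsr)
        a = su * z
        resid = w - mu - a[:, None]
        ll = -0.5 * np.sum((resid / sr) ** 2) - 2.0 * n * lsr
        g_resid = resid / sr**2  # dll/d(mu + a_i) per cell
        grad = np.empty(dim)
        grad[0] = np.sum(g_resid) - mu / ms**2
        row = g_resid.sum(axis=1)
        grad[3:] = row * su - z
        grad[1] = np.sum(row * z) * su - (su / ss) ** 2 + 1.0
        grad[2] = np.sum((resid / sr) ** 2) - 2.0 * n - (sr / ss) ** 2 + 1.0
        lp = (
            ll
            - 0.5 * (mu / ms) ** 2
            - 0.5 * (su / ss) ** 2
            + lsu
            - 0.5 * (sr / ss) ** 2
            + lsr
            - 0.5 * np.sum(z**2)
        )
        return lp, grad

    x0 = np.zeros(dim)
    x0[1] = np.log(0.7)
    x0[2] = np.log(0.7)
    res = sample_hmc(
        logp_grad,
        x0,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        seed=seed,
        target_accept=target_accept,
        max_leapfrog=max_leapfrog,
        jitter=0.05,
    )
    d = res.draws
    su = np.exp(d[:, :, 1])
    sr = np.exp(d[:, :, 2])
    draws = {
        "icc": su**2 / (su**2 + sr**2),
        "sd_unit": su * scale,
        "sd_resid": sr * scale,
    }
    if n_chains >= 2 and n_draws >= 4:
        worst = max(_rhat(np.asarray(a)) for a in draws.values())
        if np.isfinite(worst) and worst > rhat_threshold:
            warnings.warn(
                f"ICC fit may not have converged: max R-hat {worst:.3f} > {rhat_threshold}"
            )
    return IccPosterior(draws=draws, measure=ratings.measure, sampler=res)


def simulate_paired_ratings(
    n_units: int,
    true_icc: float,
    rng: np.random.Generator,
    *,
    grand_mean: float = 20.0,
    total_sd: float = 10.0,
    measure: str = "total_waves",
) -> PairedRatings:
    """Dual-coded data from the one-way random-effects model.

    Variance components are set so the between-unit share of
    ``total_sd**2`` equals ``true_icc``.
    """
    if not 0 < true_icc < 1:
        raise IccError("true_icc must lie strictly inside (0, 1)")
    sd_unit = total_sd * np.sqrt(true_icc)
    sd_resid = total_sd * np.sqrt(1.0 - true_icc)
    a = rng.normal(0.0, sd_unit, size=n_units)
    y = grand_mean + a[:, None] + rng.normal(0.0, sd_resid, size=(n_units, 2))
    return PairedRatings(
        measure=measure,
        unit_ids=tuple(f"trial_{i}" for i in range(n_units)),
        rater1=y[:, 0],
        rater2=y[:, 1],
    )
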