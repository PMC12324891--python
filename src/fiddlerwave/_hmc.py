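"""Gradient-based MCMC engine shared by all fitting modules.

A plain Hamiltonian Monte Carlo sampler with dual-averaging step-size
adaptation and a diagonal mass matrix estimated during warmup, in the
style of the samplers behind modern Bayesian model-fitting tools.  The
number of leapfrog steps is jittered uniformly per iteration, which
avoids the resonance pathologies of a fixed trajectory length while
keeping the implementation small and auditable.

Models supply ``logp_grad(x) -> (log posterior, gradient)``; everything
here is model-agnostic.  Sampling is bitwise-reproducible given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class SamplerResult:
    """Posterior draws and sampler metadata.

    ``draws`` has shape (n_chains, n_draws, dim); warmup is discarded.
    """

    draws: np.ndarray
    accept_rate: np.ndarray
    step_size: np.ndarray
    n_warmup: int
    seed: int
    divergences: np.ndarray


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
):
    """Volume-preserving leapfrog integration of Hamiltonian dynamics."""
    x = x.copy()
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return x, p, -np.inf, grad, False
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return x, p, lp, grad, True


def _initial_step_size(logp_grad: LogpGrad, x: np.ndarray, inv_mass, rng) -> float:
    """Heuristic doubling/halving search for a step size with ~50% accept."""
    eps = 0.1
    lp0, grad0 = logp_grad(x)
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(p0**2 * inv_mass)
    _, p1, lp1, _, ok = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
    log_ratio = (lp1 - 0.5 * np.sum(p1**2 * inv_mass)) - h0 if ok else -np.inf
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _, ok = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
        log_ratio = (lp1 - 0.5 * np.sum(p1**2 * inv_mass)) - h0 if ok else -np.inf
        if (direction == 1.0 and log_ratio <= np.log(0.5)) or (
            direction == -1.0 and log_ratio >= np.log(0.5)
        ):
            break
    return float(eps)


def _sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float,
    max_leapfrog: int,
):
    dim = x0.size
    x = np.asarray(x0, dtype=float).copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")
    inv_mass = np.ones(dim)

    eps = _initial_step_size(logp_grad, x, inv_mass, rng)
    # dual-averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # mass-matrix adaptation windows: estimate posterior variances from
    # the middle of warmup, updating twice
    w_lo = max(1, int(0.25 * n_warmup))
    updates = sorted({max(2, int(0.5 * n_warmup)), max(3, int(0.8 * n_warmup))})
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_accept = 0
    n_div = 0
    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(p0**2 * inv_mass)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        x1, p1, lp1, grad1, ok = _leapfrog(logp_grad, x, p0, grad, eps, n_steps, inv_mass)
        if ok:
            h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass)
            log_alpha = min(0.0, h1 - h0)
            alpha = np.exp(log_alpha)
        else:
            alpha = 0.0
            if not warming:
                n_div += 1
        if rng.random() < alpha:
            x, lp, grad = x1, lp1, grad1
            if not warming:
                n_accept += 1

        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= w_lo:
                window.append(x.copy())
            if (it + 1) in updates and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                n_w = len(window)
                # regularise towards unit scale as Stan does
                inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                window = []
                eps = _initial_step_size(logp_grad, x, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if adapt_count > 0 else eps
        else:
            draws[it - n_warmup] = x

    return draws, n_accept / max(1, n_draws), eps, n_div


def sample_hmc(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    *,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    target_accept: float = 0.85,
    max_leapfrog: int = 24,
    jitter: float = 0.0,
) -> SamplerResult:
    """Run ``n_chains`` independent HMC chains from (jittered) ``x0``.

    ``x0`` may be one vector (all chains start there, plus optional
    Gaussian jitter of scale ``jitter``) or an (n_chains, dim) array of
    per-chain starts.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if x0.shape[0] == 1 and n_chains > 1:
        x0 = np.repeat(x0, n_chains, axis=0)
    if x0.shape[0] != n_chains:
        raise ValueError("x0 must supply one start or one per chain")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chains)
    all_draws, rates, steps, divs = [], [], [], []
    for c in range(n_chains):
        rng = np.random.default_rng(children[c])
        start = x0[c]
        if jitter > 0:
            start = start + jitter * rng.standard_normal(start.size)
        # extreme proposals legitimately overflow to -inf and are
        # rejected; silence the transient numpy warnings that causes
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            d, r, e, nd = _sample_chain(
                logp_grad, start, n_warmup, n_draws, rng, target_accept, max_leapfrog
            )
        all_draws.append(d)
        rates.append(r)
        steps.append(e)
        divs.append(nd)
    return SamplerResult(
        draws=np.asarray(all_draws),
        accept_rate=np.asarray(rates),
        step_size=np.asarray(steps),
        n_warmup=n_warmup,
        seed=seed,
        divergences=np.asarray(divs),
    )
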