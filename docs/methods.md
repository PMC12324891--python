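# Methods

This note documents the statistical models implemented in
`fiddlerwave`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic-data validation does
and does not demonstrate.

## Experimental design and encoding

A trial presents one focal male with a robotic rival through four
abutting 5-minute conditions: no wave, one wave speed (slow = one wave
per 2 s or fast = one wave per 1 s), no wave again, then the remaining
speed.  Robot claw size (small/large) is fixed per trial.  Blocks of
four trials cover the claw × presentation-order combinations in
randomized order.

Models use dummy coding with reference cell (no wave, small claw); the
two no-wave conditions share one factor level, so condition position
enters only through the presentation-order covariate (hurdle model
only).  Quantities for individual treatment cells are computed as
linear combinations of posterior draws, never as separate parameters.
Continuous covariates (substrate temperature, time relative to low
tide, carapace width, claw:carapace ratio) are z-scored; the
standardisation constants are computed once per fitted dataset and
carried on the fitted object so that predictions for new data reuse
the training standardisation.  The tide-time covariate is the
interval midpoint for the HMM and the trial start for the hurdle
model; temperature is trial-level in both.

## Event processing

Intervals are half-open `[t, t+5)` seconds, 0-based, anchored at the
condition-sequence start; 300 s conditions are exact multiples of the
5-s width, so no interval straddles a condition boundary.  An interval
is *retained* for the HMM only if the male was never out of view of
both cameras and never in his burrow during it; partial burrow overlap
also excludes an interval, since the male could not have waved for
part of it.  Retained intervals are split into maximal consecutive
runs (*segments*); each segment is an independent HMM sequence with
its own initial state distribution.  Whether the original analyses
bridged or broke sequences at such gaps is not documented;
re-initialisation per segment is this package's documented choice.

The number of females per interval is the maximum simultaneous count
during the interval; rival presence is binary.  Burrow use per
condition clips episodes at condition boundaries, so each condition is
credited exactly with the in-burrow seconds inside it; an episode
still open at the schedule end is closed there.

## Signalling HMM

Two hidden states: signalling and non-signalling.  Four linear
predictors, each `intercept + β·x_t + u_male`:

1. logit P(stay in signalling) from one interval to the next,
2. logit P(stay in non-signalling),
3. log emission rate in the signalling state,
4. log emission rate in the non-signalling state.

Emissions are Poisson counts per 5-s interval (negative binomial with
a shared log-dispersion parameter is available via
`fit_hmm(..., emission="negbin")`).  The transition matrix into
interval *t* is built from the covariates of interval *t*.  The
initial distribution of each segment is the stationary distribution of
its first transition matrix — parameter-free and well defined under
time-varying covariates; a uniform (0.5, 0.5) initialisation is
available via `init="uniform"`.  Covariate effects are estimated on
all four predictors, including the non-signalling emission rate.

Likelihood: scaled forward algorithm, summed over segments and males.
Gradients: forward–backward expected sufficient statistics (smoothed
state probabilities for the emission blocks, expected transition
counts for the stay blocks, plus the analytic derivative of the
stationary initial distribution), verified against finite differences
at 1e-6 relative tolerance and against exhaustive path enumeration for
short sequences at 1e-8.

Label switching is prevented by a hard ordering constraint on the two
emission-rate intercepts (signalling above non-signalling) enforced in
the posterior density, not by post-hoc relabelling; with clearly
separated rates the constraint boundary is essentially never visited.

Expected signalling-bout length for stay probability p is
`5 s / (1 − p)` — the mean of the geometric dwell time counting the
first interval.  Posterior bout-length predictions push each draw's
stay probability through this transform at each treatment cell
(continuous covariates at 0, random intercepts at 0); draws at p = 1
propagate as +inf with a warning and the HDI is taken over the finite
order statistics.

### Priors and sampling

Weakly informative regularising priors: Normal(0, 1.5) on intercepts
and coefficients on the link scale; Half-Normal(1) on random-intercept
SDs (non-centred parameterisation `u = σz`); Normal(0, 2.5) on the
negative-binomial log-dispersion when used.

All models are fitted with a Hamiltonian Monte Carlo sampler written
for this package: leapfrog integration with dual-averaging step-size
adaptation (target acceptance 0.85), a diagonal mass matrix estimated
twice during warmup from posterior draws, and a uniformly jittered
number of leapfrog steps (1–48 for the HMM, 1–24 elsewhere) to avoid
resonant trajectories.  Library defaults are 4 chains × 1000 warmup +
1000 draws; the recovery experiments use 2 chains × 500 + 500, which
the diagnostics below show is sufficient at those problem sizes.
Convergence is monitored with rank-normalised split R-hat (threshold
1.01) and bulk effective sample size; a fit exceeding the threshold
warns rather than failing silently.  Both diagnostics match the arviz
reference implementation to machine precision on fixed draws.

### A note on the rare-event intercept

The non-signalling wave rate is tiny (0.02 per 5 s ≈ one wave per
250 s), so only on the order of 100 events inform its block.  With
nine weakly-identified covariate effects, each posterior draw trades
the reference-cell intercept against its coefficients: the average of
`exp(β·x)` over observed design rows exceeds 1 for any draw with
nonzero coefficients, and the intercept compensates downward.  The
covariate-*marginalised* rate recovers the generating value; the raw
reference-cell intercept is a noisier, slightly conservative
estimator.  At the default recovery size (40 males) its posterior
mean stays within the published uncertainty interval; replicated
small-study calibration shows ≥ 70% HDI coverage for both emission
intercepts.

## Burrow-use hurdle model

Per male × condition record: entered (Bernoulli, logit link) and,
given entry, occupancy proportion (Beta with mean μ via logit link and
precision φ; shapes μφ and (1−μ)φ).  Both parts share the design
(wave speed × claw size interaction, presentation order, z-scored
trial covariates) and have independent per-male random intercepts.
The second no-wave condition contributes a second no-wave record.

Boundary proportions (a male in his burrow an entire condition) are
pulled inside the open interval with the smoothing transform
`(y(n−1) + 0.5)/n`, n = number of occupancy observations; interior
values are untouched.  The prior on log φ is Normal(0, 2.5) — wide on
the precision scale while keeping φ positive; coefficients and SDs as
in the HMM.  Empty treatment cells leave their contrasts
prior-identified and trigger a warning.  The two likelihood parts are
independent given covariates, so the total decomposes exactly into
entry and occupancy sums (asserted in tests).

## Inter-rater reliability

One-way random-effects model on dual-coded aggregate measures:
`y_ij = μ + a_i + e_ij` with `a_i ~ N(0, σ²_u)`, `e_ij ~ N(0, σ²_r)`
and `ICC = σ²_u / (σ²_u + σ²_r)`.  Counts are treated as continuous,
consistent with the classical ICC.  Ratings are standardised
internally (the ICC is invariant to common affine rescaling of both
raters' values; variance components are reported back in original
units), with Half-Normal(1) priors on both SDs on the standardised
scale.  Reported reliability labels follow the 0.5 / 0.75 / 0.9
convention (poor / moderate / good / excellent) and are configurable.

## Posterior summaries

* **HDI**: shortest contiguous window containing ⌈mass·n⌉ sorted
  draws (default mass 0.89); ties break toward the earliest window;
  below two samples no interval is defined, and for very small n the
  window is the whole range.
* **Pr(opposite)**: fraction of draws strictly on the minority side of
  zero, tagged Pr(β>0) when most mass is negative and Pr(β<0) when
  most is positive; an exact tie reports 0.5 tagged Pr(β>0).
* **Mode**: Gaussian-KDE argmax (Scott bandwidth) on a 512-point grid
  over the draw range, on the reporting scale.
* **R-hat**: rank-normalised split version by default (max of bulk and
  folded), classical split via option; zero-variance draws return NaN
  (undefined diagnostic).
* **ESS**: bulk effective sample size with Geyer's initial monotone
  sequence on split, rank-normalised chains.

Effect tables are on the link scale; response-scale cell predictions
are produced by per-draw inverse-link transforms and summarised
separately.

## Synthetic experiments

The generator composes, per trial: morphometrics and trial covariates
from truncated normal population distributions calibrated to the field
sample (claw length ≈ 44 ± 11 mm, carapace ≈ 26.6 ± 4.4 mm,
temperature ≈ 24 ± 3.6 °C, trial start ≈ ±60 min around low tide);
at most one contiguous burrow episode per condition drawn from the
hurdle truth (duration-preserving placement, so the Beta draw equals
the realised proportion exactly); memoryless out-of-view episodes
(default 0.01 starts per interval, mean 4 s); independent per-interval
female (default 0.047) and rival (default 0.02) presence; and a hidden
state chain with Poisson counts over above-ground intervals.  Default
ground-truth parameters mirror the direction pattern and magnitudes of
the fitted field study (state rates 1.4 / 0.02 waves per 5 s, a +1
log-odds fast-wave effect on staying in the signalling state, reduced
burrow entry under waving — strongest for a small-clawed rival — and
more occupancy time with a large-clawed rival); simulated males retain
roughly 190 of 240 intervals, close to the field average.

Wave events are placed uniformly at random inside their interval, so
binning a synthetic log recovers the latent counts exactly; waves are
also emitted during out-of-view gaps (which real coded video could not
contain) — those intervals are discarded by the retention rule before
any model sees them, and keeping the events makes the round-trip
invariant exact.

What the generator does **not** emulate: trial abandonment (all
simulated males are above ground at t = 0, matching the analysed
sample), fights and interrupted trials, spatial structure of the
mudflat, behaviour-dependent missingness (out-of-view episodes are
independent of the male's state), multiple burrow episodes within one
condition, and any direct dependence of male behaviour on the robot's
wave timestamps (the stimulus acts only through the wave-speed
factor; optional robot-wave events are for display).  Passing recovery
tests therefore demonstrates the correctness of the inference
machinery under the model's own assumptions — not robustness to the
model misspecifications real field data may carry.

## Problem sizes and numerical details

Recovery experiments run at 40 simulated males (≈ 7700 retained
intervals, 2 chains × 500 + 500 draws) for the HMM, 200 males for the
hurdle model, and 50 dual-coded units × 20 replicate seeds for ICC
calibration; unit tests use 8-male studies with shorter chains.  The
forward–backward kernel is numba-compiled; a 40-male fit takes on the
order of a minute on one CPU.  Degenerate inputs are rejected
explicitly: constant covariates (z-scoring), unpaired state events,
overlapping burrow episodes, empty observation streams, non-finite
linear predictors, proportions outside (0, 1] and sub-3-unit rating
sets all raise typed errors.  HMC proposals that overflow the
likelihood are rejected through the Metropolis step rather than
clipped.

## Known limitations

* Exactly two hidden states; no continuous-time formulation.
* The HMM excludes the wave × claw interaction by default (the field
  analysis dropped it); it is available via `include_interaction`.
* Out-of-view gaps break sequences; information in the gap length is
  ignored.
* The Beta hurdle has no zero-one inflation; full-condition occupancy
  relies on the boundary smoothing transform.
* Single-seed recovery checks are ~85–90%-power tests by construction;
  calibration statements are made over replicates.
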