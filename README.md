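# fiddlerwave

Bayesian analysis of flexible sexual signalling in fiddler crabs.

Male fiddler crabs (*Afruca tangeri*) court females by repeatedly waving
their enlarged major claw, and trade signalling time against time spent
in their burrow, where they can neither see nor be seen.  In
robot-rival field experiments a biomimetic rival of manipulated claw
size waves at controlled speeds (none / one wave per 2 s / one wave per
s) through four 5-minute conditions per trial, and the focal male's
behaviour is video-coded into an ethogram event log.  `fiddlerwave`
implements the full analysis pipeline for such experiments, for
behavioural ecologists who want the bout-level structure of a
repetitive display rather than raw rate summaries:

* **Event processing** — ethogram logs (point and state events in
  seconds) are binned into 5-s intervals with wave counts and social
  context, discarding intervals in which the male was out of view or in
  his burrow, and summarised into per-condition burrow-use records.
* **Signalling HMM** — a two-state hidden Markov model (signalling /
  non-signalling) with Poisson wave-count emissions.  Four linear
  predictors carry fixed effects and per-male random intercepts:

  logit P(stay signalling), logit P(stay non-signalling),
  log λ_signalling, log λ_non-signalling,

  each as `intercept + β·x_t + u_male` with interval-specific
  covariates x_t (robot wave speed, robot claw size, females/rival in
  view, z-scored temperature, tide time, carapace width, claw:carapace
  ratio).  The likelihood is the scaled forward algorithm over
  segments of consecutive retained intervals; expected signalling-bout
  length is `5 s / (1 − P(stay))`.
* **Burrow-use hurdle model** — per condition, burrow entry is
  Bernoulli (logit link) and, given entry, the occupancy proportion is
  Beta with mean μ (logit link) and precision φ, both parts with
  treatment interactions and male random intercepts.
* **Inter-rater reliability** — Bayesian one-way random-effects ICC,
  `ICC = σ²_unit / (σ²_unit + σ²_resid)`, for dual-coded measures.
* **Posterior reporting** — 89% highest-density intervals, KDE
  posterior modes, Pr(β > 0)/Pr(β < 0) direction probabilities,
  rank-normalised split R-hat and bulk effective sample size.

All models are fitted by the package's Hamiltonian Monte Carlo engine
(dual-averaging step size, diagonal mass adaptation, analytic
gradients, forward–backward score functions for the HMM) and are
bitwise reproducible given a seed.  A synthetic-experiment generator
(`fiddlerwave.simulate`) produces complete studies — randomized-block
metadata, condition schedules and event logs — from known ground-truth
parameters, so every stage is validated by parameter recovery.

## Worked example

Simulate a small two-block study (8 males, ~1600 clean intervals), run
the event-processing pipeline, and fit the signalling HMM:

```python
import numpy as np
from fiddlerwave import (
    SimulationConfig, simulate_study, study_intervals,
    prepare_hmm_data, fit_hmm, predict_bout_lengths, summarize,
)

study = simulate_study(SimulationConfig(n_blocks=2), seed=42)   # 8 males
intervals = study_intervals(study)
data = prepare_hmm_data(intervals, study.metadata)
print(f"{data.n_intervals} retained 5-s intervals from {data.n_males} males")

post = fit_hmm(data, seed=1, n_chains=2, n_warmup=300, n_draws=300)
rates = summarize(
    {name: np.exp(np.asarray(post.draws[f"rate_{name}_intercept"]))
     for name in ("sig", "non")}
)
print(rates[["parameter", "mean", "hdi_low", "hdi_high", "rhat"]].round(3))

bouts = predict_bout_lengths(post)
print(bouts[["parameter", "mode", "hdi_low", "hdi_high"]].round(1))
```

Output:

```
1588 retained 5-s intervals from 8 males
parameter  mean  hdi_low  hdi_high  rhat
      sig 1.157    0.803     1.410 1.008
      non 0.053    0.010     0.093 1.007
parameter  mode  hdi_low  hdi_high
  no_wave  19.3     12.9      34.1
     slow  17.2     11.0      30.0
     fast  31.4     16.3      57.5
```

The two emission rates (waves per 5 s at the reference cell) are
cleanly separated — an active display state near 1.2 waves per 5 s and
a near-silent state — and this small study was generated with a
positive fast-wave effect on the stay-signalling probability, which
the bout-length predictions pick up: the posterior-mode bout lasts
about 31 s when the rival waves fast versus about 19 s when it does
not wave, with 89% HDIs from the same posterior draws.

A command-line interface wraps the same functions
(`fiddlerwave simulate | prepare | fit-hmm | fit-hurdle | icc | report`);
every command reads and writes plain CSV.

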