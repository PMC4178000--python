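# Methods

## Problem and data structure

The package analyses detection/non-detection data from a two-gear reef
survey design: at each hard-bottom site a baited chevron trap and a
trap-mounted video camera are deployed simultaneously for ~90 minutes.
The trap yields one replicate sample (the catch); the camera footage is
examined as 41 one-second snapshots taken every 30 s, used either
*pooled* (a single binary sample: any snapshot positive) or
*disaggregated* (41 replicate binary samples).  Simultaneous gears
guarantee the closure assumption across replicates: the site's occupancy
or abundance state cannot change between them.

A site record carries the two detection outcomes plus the covariates
used by the sub-models: year (2010/2011), depth (m), latitude (°N),
bottom temperature (°C), three-level classes for live-bottom cover, hard
substrate and relief, soak time (min), current direction relative to the
trap mouth (toward/perpendicular/away), current speed (low/high) and
turbidity (low/high).

## Model families

**Basic occupancy.**  `z_i ~ Bernoulli(ψ_i)` and
`y_ij ~ Binomial(k_j, z_i p_ij)`.  Logit-linear predictors:

* occupancy: intercept + 15 effects (yr2011, depth, depth², lat, lat²,
  temp, temp², livebot.l/m/h, hardsub.l/m/h, relief.m/h);
* chevron detection: intercept + 6 effects (temp, temp², soak, cdir.p,
  cdir.a, cspeed);
* camera detection: intercept + 4 effects (turb.h, cdir.p, cdir.a,
  cspeed), optionally plus a site random effect
  `ε_i ~ Normal(0, σ_ε)` inside the logit.

**Royle–Nichols.**  `N_i ~ Poisson(λ_i)` with `log λ_i` given by the same
occupancy-side linear predictor (optionally plus `ε_i` for extra-Poisson
dispersion), and species detection `p_ij = 1 − (1 − r_ij)^{N_i}` where the
*individual* detection probabilities `r_ij` take the two detection linear
predictors.  Random-effect variants are restricted to disaggregated
camera data, where the replicate structure makes them identifiable.

All continuous covariates are centred and scaled by one sample SD.
Quadratic terms are formed by squaring the *standardized* base covariate
and then standardizing the square (configurable via
`square_standardized`); this keeps every coefficient on a comparable
per-SD scale, and the stored (mean, sd) pairs let prediction grids
reproduce the training transformation exactly.

## Priors, model averaging, MCMC

All logit/log-scale coefficients carry a Student-t prior with location 0,
scale 1.566 and 7.763 degrees of freedom, chosen so that a
back-transformed intercept is approximately Uniform(0, 1); SD parameters
carry Uniform(0, 100).  Each non-intercept coefficient is multiplied by a
latent indicator `w ~ Bernoulli(0.5)` (Kuo–Mallick construction with an
independent coefficient prior): the linear predictor uses `w·β`, the
indicator is updated by Gibbs from its two-point conditional, and an
excluded coefficient is refreshed from its prior.  A covariate's
inclusion probability is the posterior mean of its indicator; >50% is
the support threshold.  Reported parameter summaries are model-averaged:
they pool all draws of `w·β`, with excluded states contributing zero
(summaries restricted to included draws are available via
`included_only`).

The sampler is written for this model class rather than delegated to a
generic PPL: Gibbs for `z` at undetected sites, a discrete Metropolis
walk for `N` (±1 steps mixed with 10% independent proposals from the
Poisson prior, truncated at `N_max`), sequential adaptive random-walk
Metropolis for coefficients (Robbins–Monro adaptation to 44% acceptance,
frozen at the end of burn-in), vectorized per-site Metropolis for `ε`,
and Metropolis for `σ_ε`.  Likelihoods are computed in log space on
cached linear predictors (softplus/log1mexp forms; the cache is rebuilt
every 200 iterations to prevent drift).  Correctness is established
against independent oracles — exhaustive latent-state enumeration for
the marginal likelihoods and a dense grid-enumeration posterior on a
no-covariate toy — not by matching any particular sampler's draws.

Full-scale settings (3 chains × 100,000 iterations, burn-in 10,000,
thinned to every 10th) are available as `MCMCSettings.paper()`.  The
package default is a desk-scale reduction (3 × 6,000, burn-in 1,000,
thin 5), and the simulation studies in the test suite use 2 chains of
2,000–3,000 iterations; at the sample sizes involved (250–400 sites)
these reproduce posterior means to well within the tolerances being
asserted, with Gelman–Rubin R-hat (classic between/within form) checked
throughout.

`N_max` defaults to 100 — generous for mean abundances ≤ ~2 — and the
marginal-likelihood routine warns if the Poisson tail mass beyond it
exceeds 1e−8.  Initialization: `z = 1` at any detection, `N` = max
observed count + 1, coefficients 0, `σ_ε` = 1, which guarantees a finite
starting likelihood.

## Goodness of fit

The fit statistic is `Σ_i Σ_c (O_ic − E_ic)² / E_ic`, with `O_ic` the
one-hot indicator of site i's observed detection history and `E_ic` its
model cell probabilities at the point estimates (model-averaged posterior
means by default; medians optional).  Pooled data have four history
cells per site; disaggregated data have 2 × 42, and the camera-count
dimension is binned from the tail until each merged bin carries at least
`min_expected` (default 2) expected sites per chevron stratum — the
binning is fixed by the observed-data expectations and reused for all
bootstrap replicates.  The null distribution comes from a parametric
bootstrap: `n_boot` datasets simulated from the point estimates at the
observed covariates, the statistic recomputed on each, and the GOF value
reported as the exceedance proportion.  By default replicates are *not*
refitted (the expected distribution under the fitted model); a
`refit=True` option implements the stricter original procedure.  The
no-refit shortcut is slightly conservative because the point estimates
adapt to the observed data; at ~400 sites the effect is small (bootstrap
calibration checks in the test suite sit near uniform).  For
random-effect models the plug-in cell probabilities are evaluated at
`ε = 0`.  The cited procedure is the chi-square comparison of
detection-history frequencies; a deviance-based variant is deliberately
not implemented.

## Prediction

Curves and surfaces evaluate the distribution sub-model draw by draw on a
raw-scale grid standardized with the training scaling, then summarize
pointwise (mean, 2.5%, 97.5%).  Non-focal covariates sit at reference
values: continuous at their training mean, categoricals at reference
levels, year 2010 — so unlisted covariates inform only the intercept —
and quadratic partners follow their base covariate through the training
pipeline (a non-focal covariate's quadratic column therefore takes the
standardized value of 0²).  A guard refuses grids more than 5 training
SDs from the mean unless widened deliberately.  Detection summaries
report each gear's posterior at reference covariates plus per-draw
contrasts for high turbidity and current-away conditions.

## Synthetic surveys

The generator emulates the study design: depth ~ Uniform(16, 83) m,
latitude ~ Uniform(27, 32)°N, temperature ~ Normal(22, 3)°C, soak ~
Normal(90, 10) min, years split evenly, and categorical frequencies set
to plausible reef-survey mixes (e.g. livebot l/m/h = 0.4/0.4/0.2, turbid
0.3).  True coefficients act on the standardized design columns built
from the generated covariates, so fitted coefficients are directly
comparable to scenario truth.  Default intercepts sit in the fitted-study
regime (occupancy 0.45; chevron detection 0.39; camera 0.75 aggregate;
mean abundance 0.654 with r = 0.30/0.61) — calibration conveniences for
in-regime data, not ground truth.  Camera effects can be specified on the
pooled scale (converted internally to the per-snapshot rate whose 41-fold
independent aggregate matches) or on the snapshot scale directly.

Two controlled violations are provided.  *Snapshot clustering*: the 41
snapshots follow a two-state Markov chain with stationary rate equal to
the target per-snapshot probability and lag-1 correlation ρ (serial
dependence from too-short snapshot spacing); a beta-binomial alternative
with intra-class correlation ρ models schooling-type extra-binomial
variation.  *Grouped individuals* (RN): fish arrive in groups of mean
size 1 + θ drawn as 1 + Poisson(θ), with group count Poisson(λ/(1+θ)) so
mean abundance is preserved; detection operates on groups as units, and a
caught group contributes its full size to the trap catch.  Under ρ = 0
and θ = 0 the generated data satisfy every fitted-model assumption, so
full-pipeline parameter recovery is the master integration test.  What
passing tests do *not* show: robustness to spatial autocorrelation,
covariate measurement error, non-random site selection or temporal
drift, none of which the generator emulates.

## Design choices and limitations

* All three livebot and hardsub dummies are carried even though the
  levels partition the sites; the all-included state is collinear with
  the intercept, and the indicator prior regularizes it (the
  model-averaged effects remain well defined).  Relief uses level `l` as
  reference; current direction uses `toward`.
* The chevron detection column of a site table may be a count (fish
  caught) or a binary flag; the reader accepts either, thresholding at
  ≥1 for detection histories.
* Model-averaged "means" average over all draws (excluded states as
  zero); restricting to included draws is available but changes the
  estimand.
* GOF for random-effect structures uses plug-in `ε = 0`; a fully
  marginal version would require integrating the random effect in the
  cell probabilities.
* Single-season models only: no dynamics, no spatial dependence, no
  N-mixture extension to count data.
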