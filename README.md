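# gearocc

Bayesian occupancy and Royle–Nichols abundance models for **two-gear
detection/non-detection surveys**: a traditional capture gear (a baited
chevron fish trap, one replicate per deployment) paired with a
simultaneously deployed camera whose footage is examined as 41 one-second
snapshots.  Deploying both gears at once gives the replicate samples that
occupancy models need to separate *occurrence* from *imperfect detection*,
without the closure violations that repeated invasive sampling would cause
— a design of particular interest for monitoring reef fish such as red
snapper, where single-gear indices are confounded by variable detection.

The package is a library first: the importable API plus the short
narrative scripts in `examples/` are its main interface.  A thin
`gearocc` CLI (`simulate`, `fit`, `gof`, `predict`, `report`) wraps the
same workflow functions for batch use.

## Models

**Basic occupancy.**  Site `i` has latent state `z_i ~ Bernoulli(ψ_i)`;
gear `j` yields `y_ij ~ Binomial(k_j, z_i · p_ij)` with `k = 1` for the
trap and `k = 1` (pooled) or `k = 41` (disaggregated snapshots) for the
camera.  Logit-linear sub-models drive `ψ` (year, depth, depth², latitude,
latitude², temperature, temperature², substrate/relief classes), trap
detection `p_1` (temperature, soak time, current direction/speed) and
camera detection `p_2` (turbidity, current direction/speed), with an
optional site random effect on camera detection.

**Royle–Nichols abundance.**  Latent abundance `N_i ~ Poisson(λ_i)` with
`log λ_i` linear in the same covariates; species-level detection emerges
from the individual detection probability `r_ij` through
`p_ij = 1 − (1 − r_ij)^{N_i}`, so abundance variation itself generates
detection heterogeneity.

**Model averaging.**  Every non-intercept coefficient is multiplied by a
latent 0/1 inclusion indicator with prior 0.5 (Kuo–Mallick).  The
indicator's posterior mean is the covariate's *inclusion probability*
(support threshold 50%), and all reported summaries are averaged across
the visited covariate configurations.  Coefficients carry Student-t
priors (scale 1.566, 7.763 df — back-transformed intercepts are
approximately uniform on (0,1)); standard deviations carry Uniform(0, 100)
priors.  Sampling is a component-wise MCMC scheme (Gibbs for latent
occupancy and indicators, discrete Metropolis for latent abundance,
adaptive random-walk Metropolis for coefficients) with Gelman–Rubin
convergence checks.

**Goodness of fit.**  A chi-square statistic on per-site detection-history
cells, calibrated by a parametric bootstrap from the fitted point
estimates; GOF values near 0 signal lack of fit (e.g. serially correlated
snapshots breaking the disaggregated model), near 1 adequate fit.

## Worked example

```python
from scipy.special import expit
from gearocc import (SimScenario, simulate_basic, build_detection_data,
                     build_design_matrices, ModelSpec, MCMCSettings,
                     sample_posterior, summarize_fit)

records, truth = simulate_basic(SimScenario(S=300, seed=2))
data    = build_detection_data(records, "pooled")
design  = build_design_matrices(records)
samples = sample_posterior(ModelSpec(), data, design,
                           settings=MCMCSettings(n_chains=2, n_iter=3000,
                                                 burn_in=600, thin=3, seed=2))
summary = summarize_fit(samples, design)
```

Running `python examples/02_fit_basic_occupancy.py` (exactly this
analysis) prints:

```
posterior mean occupancy : 0.48 (95% CI [0.40, 0.56])
true occupancy rate      : 0.50
chevron detection p      : 0.39  (truth 0.39)
camera detection p       : 0.75  (truth 0.75)
max Gelman-Rubin R-hat   : 1.016
```

The corrected occupancy estimate recovers the simulated truth even though
the naive single-gear rates (≈0.17 trap, ≈0.35 camera — see
`examples/01_simulate_survey.py`) undercount occupied sites.  The other
examples cover covariate selection, goodness of fit under snapshot
clustering, the downward abundance bias under grouped individuals, and
prediction curves with detection-abundance thresholds.

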