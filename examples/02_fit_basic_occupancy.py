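"""Fit the basic occupancy model to a simulated survey.

The model corrects the naive detection rates for imperfect detection:
a latent Bernoulli(psi) occupancy state per site with gear-specific
conditional detection probabilities, sampled by MCMC under weakly
informative Student-t priors.
"""

import numpy as np
from scipy.special import expit

from gearocc import (MCMCSettings, ModelSpec, SimScenario, build_design_matrices,
                     build_detection_data, sample_posterior, simulate_basic,
                     summarize_fit)

records, truth = simulate_basic(SimScenario(S=300, seed=2))
data = build_detection_data(records, "pooled")
design = build_design_matrices(records)

settings = MCMCSettings(n_chains=2, n_iter=3000, burn_in=600, thin=3, seed=2)
samples = sample_posterior(ModelSpec(), data, design, settings=settings)
summary = summarize_fit(samples, design)

psi_hat = summary.derived["mean_psi"]
lo, hi = summary.derived["mean_psi_ci"]
p_chev = expit(samples.stacked("alpha")[:, 0]).mean()
p_cam = expit(samples.stacked("phi")[:, 0]).mean()

print(f"posterior mean occupancy : {psi_hat:.2f} (95% CI [{lo:.2f}, {hi:.2f}])")
print(f"true occupancy rate      : {np.mean(truth.z):.2f}")
print(f"chevron detection p      : {p_chev:.2f}  (truth 0.39)")
print(f"camera detection p       : {p_cam:.2f}  (truth 0.75)")
print(f"max Gelman-Rubin R-hat   : {np.nanmax(summary.rhat.to_numpy()):.3f}")
print()
print("The corrected occupancy estimate recovers the simulated truth even "
      "though each gear alone would have undercounted occupied sites; "
      "R-hat near 1 indicates the chains mixed.")
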