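"""Royle-Nichols abundance model and the clustering bias.

The RN model explains detection heterogeneity through latent site
abundance N ~ Poisson(lambda): species detection is 1-(1-r)^N with r the
individual detection probability.  When fish move in groups that are
detected jointly, the model perceives groups as individuals and
underestimates abundance — demonstrated here by fitting to independent
and to clustered simulations of the same mean abundance.
"""

import math
import numpy as np

from gearocc import (MCMCSettings, ModelSpec, SimScenario, build_design_matrices,
                     build_detection_data, sample_posterior, simulate_rn,
                     summarize_fit)

lam_true = 1.5
beta = np.r_[math.log(lam_true), np.zeros(15)]
settings = MCMCSettings(n_chains=2, n_iter=2000, burn_in=500, thin=3, seed=5)
spec = ModelSpec(family="royle_nichols", camera_mode="pooled", N_max=60)

for theta, label in ((0.0, "independent fish"), (1.5, "grouped fish")):
    scenario = SimScenario(S=300, family="royle_nichols", seed=5, beta=beta,
                           group_size_dispersion=theta)
    records, truth = simulate_rn(scenario)
    data = build_detection_data(records, "pooled")
    design = build_design_matrices(records)
    samples = sample_posterior(spec, data, design, settings=settings,
                               store_latent=False)
    lam_hat = summarize_fit(samples, design).derived["mean_lambda"]
    print(f"{label:<17} true mean N {np.mean(truth.N):.2f}  "
          f"lambda-hat {lam_hat:.2f}")

print()
print(f"(true lambda = {lam_true}.)  With independent individuals the "
      "estimate is close to truth; with jointly-detected groups it drops "
      "well below — the direction of bias expected when the individual-"
      "independence assumption fails.")
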