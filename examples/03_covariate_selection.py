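"""Bayesian indicator-variable model averaging for covariate support.

Every candidate covariate effect is multiplied by a latent 0/1 inclusion
indicator with prior probability 0.5.  The posterior mean of each
indicator is that covariate's inclusion probability; values above 50%
mark covariates the data support.  Here depth has a real effect
(standardized beta = -1) and temperature has none.
"""

import numpy as np

from gearocc import (MCMCSettings, ModelSpec, SimScenario, build_design_matrices,
                     build_detection_data, inclusion_probabilities, logit,
                     sample_posterior, simulate_basic)
from gearocc.data import OCC_COLUMNS

beta = np.zeros(16)
beta[0] = logit(0.45)
beta[1 + list(OCC_COLUMNS).index("depth")] = -1.0

records, _ = simulate_basic(SimScenario(S=400, seed=3, beta=beta))
data = build_detection_data(records, "pooled")
design = build_design_matrices(records)
settings = MCMCSettings(n_chains=2, n_iter=3000, burn_in=600, thin=3, seed=3)
samples = sample_posterior(ModelSpec(), data, design, settings=settings)

incl = inclusion_probabilities(samples)
occ = incl[[f"occ:{c}" for c in ("depth", "temp", "lat", "yr2011")]]
print(occ.round(2).to_string())
print()
supported = occ[occ > 0.5].index.tolist()
print(f"supported (>50%): {supported}")
print()
print("The genuine depth effect is selected with high probability while "
      "the null covariates stay near or below their 0.5 prior.")
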