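"""Goodness of fit: pooled vs disaggregated camera data.

The chi-square/parametric-bootstrap GOF value lies in (0,1): values near
zero signal lack of fit.  Treating the 41 snapshots as independent
replicates fails when the snapshots are serially correlated; pooling them
into one binary sample remains well specified.
"""

from gearocc import (MCMCSettings, ModelSpec, SimScenario, build_design_matrices,
                     build_detection_data, parametric_bootstrap_gof,
                     sample_posterior, simulate_basic)

settings = MCMCSettings(n_chains=2, n_iter=2000, burn_in=500, thin=3, seed=4)

# snapshots with lag-1 correlation 0.6 (e.g. fish lingering in frame)
records, _ = simulate_basic(SimScenario(S=300, seed=4, snapshot_clustering=0.6))

for mode in ("pooled", "disaggregated"):
    data = build_detection_data(records, mode)
    design = build_design_matrices(records)
    spec = ModelSpec(camera_mode=mode)
    samples = sample_posterior(spec, data, design, settings=settings,
                               store_latent=False)
    gof = parametric_bootstrap_gof(samples, data, design, n_boot=100, seed=4)
    print(f"{mode:<14} GOF p = {gof.gof_p:.2f}  "
          f"(observed stat {gof.observed_stat:.0f})")

print()
print("The pooled model fits (GOF well above 0) while the disaggregated "
      "model is rejected (GOF near 0): serial dependence among snapshots "
      "violates its binomial replication assumption.")
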