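import numpy as np
import pytest

from gearocc import (MCMCSettings, ModelSpec, SimScenario, simulate_basic,
                     build_design_matrices, build_detection_data)
from gearocc.mcmc import PosteriorSamples


@pytest.fixture(scope="session")
def basic_records():
    """A 60-site survey simulated from the basic occupancy model with
    study-like intercepts and no covariate effects."""
    records, truth = simulate_basic(SimScenario(S=60, seed=42))
    return records, truth


@pytest.fixture(scope="session")
def basic_pooled(basic_records):
    records, _ = basic_records
    return (build_detection_data(records, "pooled"),
            build_design_matrices(records))


@pytest.fixture
def quick_settings():
    return MCMCSettings(n_chains=2, n_iter=1200, burn_in=300, thin=3, seed=1)


def make_samples(model_spec=None, n_chains=2, n_draws=50, beta=None, alpha=None,
                 phi=None, w_occ=1.0, w_chev=1.0, w_cam=1.0, jitter=0.0,
                 seed=0) -> PosteriorSamples:
    """Posterior-samples container with controlled draw values, for testing
    summarization and prediction independently of the sampler."""
    rng = np.random.default_rng(seed)

    def block(template, size):
        base = np.zeros(size) if template is None else np.asarray(template, float)
        a = np.tile(base, (n_chains, n_draws, 1)).astype(float)
        if jitter:
            a = a + jitter * rng.standard_normal(a.shape)
        return a

    draws = {
        "beta": block(beta, 16),
        "alpha": block(alpha, 7),
        "phi": block(phi, 5),
        "w_occ": np.full((n_chains, n_draws, 15), float(w_occ)),
        "w_chev": np.full((n_chains, n_draws, 6), float(w_chev)),
        "w_cam": np.full((n_chains, n_draws, 4), float(w_cam)),
        "sigma_eps": np.zeros((n_chains, n_draws)),
    }
    settings = MCMCSettings(n_chains=n_chains, n_iter=n_draws, thin=1,
                            burn_in=0, seed=seed)
    return PosteriorSamples(model_spec=model_spec or ModelSpec(),
                            settings=settings, draws=draws)
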