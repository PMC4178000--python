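"""Chi-square goodness-of-fit with parametric bootstrap.

The fit statistic compares each site's observed detection history against
the history-cell probabilities implied by the fitted model's point
estimates (model-averaged posterior means by default).  Its null
distribution is obtained by a parametric bootstrap: datasets are simulated
from the point estimates at the observed covariates and the statistic is
recomputed on each.  The GOF value is the proportion of bootstrap
statistics at least as large as the observed one — values near zero signal
lack of fit, values near one adequate fit.

With pooled camera data the history cells are the four joint outcomes
(chevron x camera in {0,1}^2).  With disaggregated data the camera
dimension is the snapshot count 0..41; sparse count cells are pooled from
the tail until each merged bin carries enough expected mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import binom, poisson

from .data import DetectionData, DesignMatrices, N_SNAPSHOTS
from .mcmc import ModelSpec, PosteriorSamples, MCMCSettings, sample_posterior
from .models import inv_logit

__all__ = ["GofResult", "point_estimates", "history_cell_probs",
           "camera_bins", "chisq_stat", "simulate_from_estimates",
           "parametric_bootstrap_gof"]


@dataclass
class GofResult:
    observed_stat: float
    boot_stats: np.ndarray
    gof_p: float
    n_boot: int
    seed: int
    refit: bool = False
    refit_failures: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["boot_stats"] = [float(v) for v in self.boot_stats]
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GofResult":
        d = json.loads(Path(path).read_text())
        d["boot_stats"] = np.asarray(d["boot_stats"], dtype=float)
        return cls(**d)

    def report_row(self, model_spec: ModelSpec, rhat: float | None = None) -> str:
        gr = f"{rhat:.2f}" if rhat is not None else "-"
        return (f"{model_spec.family:<14} {model_spec.camera_mode:<14} "
                f"{'yes' if model_spec.random_effect else 'no':<3} "
                f"G-R {gr}  GOF {self.gof_p:.2f}")


def point_estimates(samples: PosteriorSamples, statistic: str = "mean") -> dict:
    """Model-averaged point estimates (posterior mean or median) of the
    effective coefficient vectors."""
    agg = np.mean if statistic == "mean" else np.median
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    return {
        "beta": agg(samples.effective_coefficients("occ"), axis=0),
        "alpha": agg(samples.effective_coefficients("chev"), axis=0),
        "phi": agg(samples.effective_coefficients("cam"), axis=0),
    }


def _site_probs(estimates: dict, design: DesignMatrices):
    psi_lp = estimates["beta"][0] + design.X_occ @ estimates["beta"][1:]
    p1 = inv_logit(estimates["alpha"][0] + design.X_chev @ estimates["alpha"][1:])
    p2 = inv_logit(estimates["phi"][0] + design.X_cam @ estimates["phi"][1:])
    return psi_lp, p1, p2


def history_cell_probs(estimates: dict, model_spec: ModelSpec,
                       design: DesignMatrices,
                       site_i: int | None = None) -> np.ndarray:
    """Per-site history-cell probabilities under the point estimates.

    Returns shape (S, 4) for pooled data (cell order 00, 01, 10, 11 in
    chevron-camera outcome) or (S, 2 * 42) for disaggregated data (cell
    index = chevron * 42 + camera count).  Each row sums to one.  With
    ``site_i`` a single site's vector is returned.
    """
    psi_lp, p1, p2 = _site_probs(estimates, design)
    k2 = 1 if model_spec.camera_mode == "pooled" else N_SNAPSHOTS
    S = design.n_sites
    counts = np.arange(k2 + 1)

    if model_spec.family == "basic":
        psi = inv_logit(psi_lp)
        cam_pmf = binom.pmf(counts[None, :], k2, p2[:, None])      # (S, k2+1)
        chev_pmf = np.stack([1 - p1, p1], axis=1)                  # (S, 2)
        occ = psi[:, None, None] * chev_pmf[:, :, None] * cam_pmf[:, None, :]
        cells = occ
        cells[:, 0, 0] += 1 - psi
    else:
        lam = np.exp(psi_lp)
        Ns = np.arange(model_spec.N_max + 1)
        wN = poisson.pmf(Ns[None, :], lam[:, None])                # (S, N+1)
        wN = wN / wN.sum(axis=1, keepdims=True)                    # renormalize tail
        q1 = (1 - p1)[:, None] ** Ns[None, :]                      # (S, N+1)
        pd1 = 1 - q1
        q2pow = (1 - p2)[:, None] ** Ns[None, :]
        pd2 = 1 - q2pow                                            # per-replicate
        cam_pmf = binom.pmf(counts[None, None, :], k2, pd2[:, :, None])
        chev_pmf = np.stack([q1, pd1], axis=2)                     # (S, N+1, 2)
        cells = np.einsum("sn,snc,snk->sck", wN, chev_pmf, cam_pmf)
    out = cells.reshape(S, -1)
    out = out / out.sum(axis=1, keepdims=True)
    return out[site_i] if site_i is not None else out


def camera_bins(cell_probs: np.ndarray, mode: str,
                min_expected: float = 2.0) -> list[np.ndarray]:
    """Bin the camera-count dimension so every merged bin carries expected
    mass (summed over sites and chevron outcomes) of at least
    ``min_expected`` per chevron stratum, merging from the tail.

    Pooled data keep their two single-count cells.  Returns a list of
    arrays of camera-count values forming each bin.
    """
    n_cam = cell_probs.shape[1] // 2
    if mode == "pooled":
        return [np.array([0]), np.array([1])]
    grid = cell_probs.reshape(-1, 2, n_cam).sum(axis=(0, 1))   # expected per count
    bins, current, mass = [], [], 0.0
    for c in range(n_cam):
        current.append(c)
        mass += grid[c]
        if mass >= 2 * min_expected:
            bins.append(np.array(current))
            current, mass = [], 0.0
    if current:
        if bins:
            bins[-1] = np.concatenate([bins[-1], np.array(current)])
        else:
            bins.append(np.array(current))
    return bins


def chisq_stat(detection_data: DetectionData, cell_probs: np.ndarray,
               bins: list[np.ndarray] | None = None,
               min_expected: float = 2.0) -> float:
    """Chi-square-type fit statistic: sum over sites and (binned) cells of
    (O - E)^2 / E with O each site's observed history indicator and E its
    cell probabilities."""
    S = detection_data.n_sites
    n_cam = cell_probs.shape[1] // 2
    if bins is None:
        bins = camera_bins(cell_probs, detection_data.mode, min_expected)
    probs3 = cell_probs.reshape(S, 2, n_cam)
    E = np.stack([probs3[:, :, b].sum(axis=2) for b in bins], axis=2)  # (S,2,nb)
    y1 = detection_data.y[:, 0]
    y2 = detection_data.y[:, 1]
    bin_of = np.empty(n_cam, dtype=np.int64)
    for bi, b in enumerate(bins):
        bin_of[b] = bi
    O = np.zeros_like(E)
    O[np.arange(S), y1, bin_of[y2]] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (O - E) ** 2 / E
    return float(contrib[E > 0].sum())


def simulate_from_estimates(estimates: dict, model_spec: ModelSpec,
                            design: DesignMatrices, n_boot: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Simulate n_boot detection datasets from the point estimates at the
    observed covariates; returns y of shape (n_boot, S, 2)."""
    psi_lp, p1, p2 = _site_probs(estimates, design)
    S = design.n_sites
    k2 = 1 if model_spec.camera_mode == "pooled" else N_SNAPSHOTS
    if model_spec.family == "basic":
        psi = inv_logit(psi_lp)
        z = rng.random((n_boot, S)) < psi
        y1 = rng.binomial(1, z * p1)
        y2 = rng.binomial(k2, z * p2)
    else:
        lam = np.exp(psi_lp)
        N = rng.poisson(lam, size=(n_boot, S))
        pd1 = 1 - (1 - p1) ** N
        pd2 = 1 - (1 - p2) ** N
        y1 = rng.binomial(1, pd1)
        y2 = rng.binomial(k2, pd2)
    return np.stack([y1, y2], axis=2)


def parametric_bootstrap_gof(fit: PosteriorSamples | dict,
                             detection_data: DetectionData,
                             design: DesignMatrices,
                             n_boot: int = 200,
                             refit: bool = False,
                             seed: int = 0,
                             model_spec: ModelSpec | None = None,
                             point_statistic: str = "mean",
                             min_expected: float = 2.0,
                             refit_settings: MCMCSettings | None = None) -> GofResult:
    """Parametric-bootstrap goodness of fit.

    ``fit`` is either a PosteriorSamples (point estimates are its
    model-averaged posterior means, or medians via ``point_statistic``) or
    an explicit estimates dict with keys beta/alpha/phi.  By default the
    bootstrap statistics reuse the fitted point estimates (the expected
    distribution under the fitted model); ``refit=True`` refits the model
    to every bootstrap dataset, the stricter original procedure.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if isinstance(fit, PosteriorSamples):
        model_spec = fit.model_spec
        estimates = point_estimates(fit, point_statistic)
    else:
        if model_spec is None:
            raise ValueError("model_spec is required when fit is an estimates dict")
        estimates = fit
    cell_probs = history_cell_probs(estimates, model_spec, design)
    bins = camera_bins(cell_probs, detection_data.mode, min_expected)
    observed = chisq_stat(detection_data, cell_probs, bins)

    rng = np.random.default_rng([seed, 17])
    y_boot = simulate_from_estimates(estimates, model_spec, design, n_boot, rng)
    boot_stats = np.empty(n_boot)
    refit_failures = 0
    for b in range(n_boot):
        data_b = DetectionData(mode=detection_data.mode, y=y_boot[b],
                               k=detection_data.k)
        if refit:
            try:
                settings = refit_settings or MCMCSettings(
                    n_chains=1, n_iter=1500, burn_in=500, thin=2, seed=seed + b)
                samp = sample_posterior(model_spec, data_b, design,
                                        settings=settings, store_latent=False)
                est_b = point_estimates(samp, point_statistic)
                probs_b = history_cell_probs(est_b, model_spec, design)
                boot_stats[b] = chisq_stat(data_b, probs_b, bins)
                continue
            except Exception:
                refit_failures += 1
        boot_stats[b] = chisq_stat(data_b, cell_probs, bins)
    gof_p = float(np.mean(boot_stats >= observed))
    return GofResult(observed_stat=observed, boot_stats=boot_stats,
                     gof_p=gof_p, n_boot=n_boot, seed=seed, refit=refit,
                     refit_failures=refit_failures)
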