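"""Likelihoods and link functions for the two model families.

Two hierarchical models share the same two-gear observation layer:

* the basic occupancy model — a latent Bernoulli occupancy state z_i with
  probability psi_i, and gear-specific conditional detection probabilities
  p_ij on the logit scale; and
* the Royle-Nichols model — a latent Poisson abundance N_i with mean
  lambda_i on the log scale, where the species-level detection probability
  emerges from the individual detection probability r_ij through
  p_ij = 1 - (1 - r_ij)^N_i.

All site likelihoods are computed in log space; marginal forms integrate
the latent state out exactly (Bernoulli) or by truncated summation
(Poisson, with a tail-mass guard).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import poisson

__all__ = [
    "inv_logit", "logit", "BasicOccParams", "RNParams",
    "occupancy_prob", "detection_prob_chevron", "detection_prob_camera",
    "species_detection_from_individual", "min_abundance_for_detection",
    "binom_logpmf", "basic_site_loglik", "basic_site_marginal_loglik",
    "rn_site_marginal_loglik",
]

N_MAX_DEFAULT = 100


def inv_logit(x):
    """Inverse logit (logistic) link; maps the real line to (0, 1)."""
    return expit(x)


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclass
class BasicOccParams:
    """Parameters of the basic occupancy model.

    beta: occupancy coefficients (intercept + 15 covariate effects);
    alpha: chevron detection (intercept + 6); phi: camera detection
    (intercept + 4); eps: optional per-site random effect on camera
    detection (logit scale), with standard deviation sigma_eps.
    """

    beta: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray
    eps: np.ndarray | None = None
    sigma_eps: float = 0.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")


@dataclass
class RNParams:
    """Parameters of the Royle-Nichols model.

    beta acts on log mean abundance; alpha/phi act on the logit of the
    *individual* detection probabilities r. eps is an optional per-site
    log-abundance random effect. N_max truncates the Poisson marginal.
    """

    beta: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray
    eps: np.ndarray | None = None
    sigma_eps: float = 0.0
    N_max: int = N_MAX_DEFAULT

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.N_max < 1:
            raise ValueError("N_max must be >= 1")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")


def _linear_predictor(coef: np.ndarray, w: np.ndarray | None, X: np.ndarray) -> np.ndarray:
    coef = np.asarray(coef, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != coef.size - 1:
        raise ValueError(
            f"design matrix has {X.shape[1]} columns but coefficient vector "
            f"implies {coef.size - 1}"
        )
    slopes = coef[1:]
    if w is not None:
        w = np.asarray(w, dtype=float)
        if w.size != slopes.size:
            raise ValueError("inclusion mask length must match non-intercept coefficients")
        slopes = w * slopes
    return coef[0] + X @ slopes


def occupancy_prob(beta, w, X_occ) -> np.ndarray:
    """Per-site occupancy probability psi_i under inclusion mask w.

    The intercept is never masked; each slope is multiplied by its 0/1
    inclusion indicator before entering the logit.
    """
    return expit(_linear_predictor(beta, w, X_occ))


def detection_prob_chevron(alpha, w, X_chev) -> np.ndarray:
    """Chevron-trap detection probability (p for basic, r for RN)."""
    return expit(_linear_predictor(alpha, w, X_chev))


def detection_prob_camera(phi, w, X_cam, eps=None) -> np.ndarray:
    """Camera-trap detection probability, with optional site random effect
    eps added inside the logit."""
    lp = _linear_predictor(phi, w, X_cam)
    if eps is not None:
        lp = lp + np.asarray(eps, dtype=float)
    return expit(lp)


def species_detection_from_individual(r, N):
    """Species-level detection probability from individual probability r and
    abundance N: p = 1 - (1 - r)^N."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > 1):
        raise ValueError("individual detection probability must lie in [0, 1]")
    N_arr = np.asarray(N, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.expm1(N_arr * np.log1p(-r_arr))
    out = np.where(r_arr >= 1.0, (N_arr > 0).astype(float), out)
    return float(out) if out.ndim == 0 else out


def min_abundance_for_detection(r: float, threshold: float) -> int:
    """Smallest abundance N with species detection 1-(1-r)^N >= threshold.

    Closed form ceil(log(1-threshold)/log(1-r)), with an explicit check
    against the one-off error the ceiling can produce at representable
    boundaries.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if not 0 < r <= 1:
        raise ValueError("no finite abundance achieves the threshold when r = 0")
    if r == 1:
        return 1
    n = max(1, math.ceil(math.log1p(-threshold) / math.log1p(-r)))
    while n > 1 and species_detection_from_individual(r, n - 1) >= threshold:
        n -= 1
    while species_detection_from_individual(r, n) < threshold:
        n += 1
    return n


def binom_logpmf(y, k, p):
    """log Binomial(y | k, p), safe at p in {0, 1}."""
    y = np.asarray(y, dtype=float)
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    out = gammaln(k + 1) - gammaln(y + 1) - gammaln(k - y + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(p), 0.0)
        term2 = np.where(k - y > 0, (k - y) * np.log1p(-p), 0.0)
    out = out + term1 + term2
    return np.where(((p == 0) & (y > 0)) | ((p == 1) & (y < k)), -np.inf, out)


def basic_site_loglik(params: BasicOccParams, w_all, detection_data,
                      X_occ, X_chev, X_cam, site_i: int, z_i: int) -> float:
    """Log-likelihood of site i's two-gear history conditional on occupancy
    state z_i: sum_j log Binomial(y_ij | k_j, z_i * p_ij)."""
    if z_i not in (0, 1):
        raise ValueError("z_i must be 0 or 1")
    y = detection_data.y[site_i]
    k = detection_data.k
    if z_i == 0:
        return 0.0 if (y == 0).all() else -np.inf
    p1, p2 = _site_detprobs_basic(params, w_all, X_chev, X_cam, site_i)
    return float(binom_logpmf(y[0], k[0], p1) + binom_logpmf(y[1], k[1], p2))


def _site_detprobs_basic(params, w_all, X_chev, X_cam, site_i):
    _, w_chev, w_cam = w_all
    p1 = detection_prob_chevron(params.alpha, w_chev, X_chev[site_i:site_i + 1])[0]
    eps_i = params.eps[site_i] if params.eps is not None else None
    p2 = detection_prob_camera(params.phi, w_cam, X_cam[site_i:site_i + 1], eps_i)[0]
    return p1, p2


def basic_site_marginal_loglik(params: BasicOccParams, w_all, detection_data,
                               X_occ, X_chev, X_cam, site_i: int) -> float:
    """Marginal log-likelihood of site i, integrating z_i over
    Bernoulli(psi_i): log[psi * L(z=1) + (1-psi) * 1{all zero}]."""
    w_occ = w_all[0]
    psi = occupancy_prob(params.beta, w_occ, X_occ[site_i:site_i + 1])[0]
    ll1 = basic_site_loglik(params, w_all, detection_data,
                            X_occ, X_chev, X_cam, site_i, 1)
    y = detection_data.y[site_i]
    branches = [np.log(psi) + ll1] if psi > 0 else []
    if (y == 0).all() and psi < 1:
        branches.append(np.log1p(-psi))
    if not branches:
        return -np.inf
    return float(logsumexp(branches))


def rn_site_marginal_loglik(params: RNParams, w_all, detection_data,
                            X_occ, X_chev, X_cam, site_i: int,
                            tail_tol: float = 1e-8) -> float:
    """Marginal log-likelihood of site i under the Royle-Nichols model,
    summing the latent abundance N over 0..N_max.

    Warns when the Poisson prior mass beyond N_max exceeds ``tail_tol``.
    """
    w_occ, w_chev, w_cam = w_all
    lam_lp = _linear_predictor(params.beta, w_occ, X_occ[site_i:site_i + 1])[0]
    if params.eps is not None:
        lam_lp = lam_lp + params.eps[site_i]
    lam = np.exp(lam_lp)
    r1 = detection_prob_chevron(params.alpha, w_chev, X_chev[site_i:site_i + 1])[0]
    r2 = detection_prob_camera(params.phi, w_cam, X_cam[site_i:site_i + 1])[0]

    tail = float(poisson.sf(params.N_max, lam))
    if tail > tail_tol:
        warnings.warn(
            f"Poisson tail mass beyond N_max={params.N_max} is {tail:.2e} "
            f"(> {tail_tol:.0e}) at lambda={lam:.3g}; increase N_max",
            RuntimeWarning, stacklevel=2,
        )
    Ns = np.arange(params.N_max + 1)
    log_prior = poisson.logpmf(Ns, lam)
    y = detection_data.y[site_i]
    k = detection_data.k
    p1 = species_detection_from_individual(r1, Ns)
    p2 = species_detection_from_individual(r2, Ns)
    ll = binom_logpmf(y[0], k[0], p1) + binom_logpmf(y[1], k[1], p2)
    return float(logsumexp(log_prior + ll))
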