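import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp
from scipy.stats import poisson

from gearocc import (BasicOccParams, RNParams, basic_site_loglik,
                     basic_site_marginal_loglik, detection_prob_camera,
                     detection_prob_chevron, inv_logit, logit,
                     min_abundance_for_detection, occupancy_prob,
                     rn_site_marginal_loglik, species_detection_from_individual)
from gearocc.data import DetectionData

HSETTINGS = dict(deadline=None, derandomize=True, max_examples=60)


def _toy_design(S, rng=None):
    rng = rng or np.random.default_rng(0)
    return (rng.standard_normal((S, 15)), rng.standard_normal((S, 6)),
            rng.standard_normal((S, 4)))


class TestLinks:
    def test_inv_logit_values(self):
        assert inv_logit(0.0) == 0.5
        assert abs(inv_logit(logit(0.3)) - 0.3) < 1e-12

    @given(st.floats(-30, 30))
    @settings(**HSETTINGS)
    def test_symmetry(self, x):
        assert abs(inv_logit(x) - (1 - inv_logit(-x))) < 1e-12


class TestLinearPredictors:
    def test_all_masked_is_intercept_only(self):
        X, _, _ = _toy_design(5)
        beta = np.r_[0.7, np.ones(15)]
        psi = occupancy_prob(beta, np.zeros(15), X)
        np.testing.assert_allclose(psi, inv_logit(0.7))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(12)
        X_occ, X_chev, X_cam = _toy_design(8, rng)
        beta = rng.standard_normal(16)
        alpha = rng.standard_normal(7)
        phi = rng.standard_normal(5)
        w_o = rng.integers(0, 2, 15)
        w_c = rng.integers(0, 2, 6)
        w_k = rng.integers(0, 2, 4)
        eps = rng.standard_normal(8)
        psi = occupancy_prob(beta, w_o, X_occ)
        p1 = detection_prob_chevron(alpha, w_c, X_chev)
        p2 = detection_prob_camera(phi, w_k, X_cam, eps)
        for i in range(8):
            lp = beta[0] + sum(w_o[m] * beta[m + 1] * X_occ[i, m] for m in range(15))
            assert abs(psi[i] - 1 / (1 + math.exp(-lp))) < 1e-12
            lp = alpha[0] + sum(w_c[m] * alpha[m + 1] * X_chev[i, m] for m in range(6))
            assert abs(p1[i] - 1 / (1 + math.exp(-lp))) < 1e-12
            lp = phi[0] + sum(w_k[m] * phi[m + 1] * X_cam[i, m] for m in range(4)) + eps[i]
            assert abs(p2[i] - 1 / (1 + math.exp(-lp))) < 1e-12

    def test_large_random_effect_saturates(self):
        X = np.zeros((1, 4))
        p = detection_prob_camera(np.zeros(5), np.zeros(4), X, eps=np.array([50.0]))
        assert p[0] > 1 - 1e-9

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            occupancy_prob(np.zeros(16), np.zeros(14), np.zeros((3, 15)))


class TestAbundanceDetectionLink:
    def test_paper_thresholds(self):
        assert species_detection_from_individual(0.61, 4) > 0.95
        assert species_detection_from_individual(0.5, 2) == pytest.approx(0.75)
        assert species_detection_from_individual(0.3, 0) == 0.0

    @pytest.mark.parametrize("r,threshold,expected", [
        (0.30, 0.95, 9), (0.61, 0.95, 4), (0.999, 0.95, 1)])
    def test_min_abundance_examples(self, r, threshold, expected):
        assert min_abundance_for_detection(r, threshold) == expected

    def test_r_zero_has_no_solution(self):
        with pytest.raises(ValueError):
            min_abundance_for_detection(0.0, 0.95)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(**HSETTINGS)
    def test_min_abundance_is_tight(self, r, threshold):
        n = min_abundance_for_detection(r, threshold)
        assert species_detection_from_individual(r, n) >= threshold
        if n > 1:
            assert species_detection_from_individual(r, n - 1) < threshold

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.integers(0, 50))
    @settings(**HSETTINGS)
    def test_monotone_in_r_and_n(self, r1, r2, n):
        lo, hi = sorted((r1, r2))
        assert (species_detection_from_individual(lo, n)
                <= species_detection_from_individual(hi, n) + 1e-12)
        assert (species_detection_from_individual(r1, n)
                <= species_detection_from_individual(r1, n + 1) + 1e-12)


def _hand_binom_logpmf(y, k, p):
    if p in (0.0, 1.0):
        exact = (p == 1.0 and y == k) or (p == 0.0 and y == 0)
        return 0.0 if exact else -math.inf
    return (math.log(math.comb(k, y)) + y * math.log(p)
            + (k - y) * math.log(1 - p))


class TestBasicLikelihood:
    def _setup(self, y, mode="pooled", seed=5):
        rng = np.random.default_rng(seed)
        S = y.shape[0]
        X_occ, X_chev, X_cam = _toy_design(S, rng)
        k = np.array([1, 1]) if mode == "pooled" else np.array([1, 41])
        data = DetectionData(mode=mode, y=y, k=k)
        params = BasicOccParams(beta=0.3 * rng.standard_normal(16),
                                alpha=0.3 * rng.standard_normal(7),
                                phi=0.3 * rng.standard_normal(5))
        w_all = (np.ones(15), np.ones(6), np.ones(4))
        return params, w_all, data, X_occ, X_chev, X_cam

    def test_unoccupied_site(self):
        args = self._setup(np.array([[0, 0]]))
        assert basic_site_loglik(*args, 0, 0) == 0.0
        args = self._setup(np.array([[1, 0]]))
        assert basic_site_loglik(*args, 0, 0) == -math.inf

    def test_occupied_matches_hand_pmf(self):
        y = np.array([[1, 17], [0, 0], [1, 41]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y, mode="disaggregated")
        p1 = detection_prob_chevron(params.alpha, w_all[1], Xc)
        p2 = detection_prob_camera(params.phi, w_all[2], Xk)
        for i in range(3):
            expected = (_hand_binom_logpmf(y[i, 0], 1, p1[i])
                        + _hand_binom_logpmf(y[i, 1], 41, p2[i]))
            got = basic_site_loglik(params, w_all, data, Xo, Xc, Xk, i, 1)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_marginal_is_two_branch_logsumexp(self):
        y = np.array([[0, 0], [1, 1], [0, 1]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y)
        psi = occupancy_prob(params.beta, w_all[0], Xo)
        for i in range(3):
            branches = [math.log(psi[i]) + basic_site_loglik(
                params, w_all, data, Xo, Xc, Xk, i, 1)]
            if (y[i] == 0).all():
                branches.append(math.log(1 - psi[i]))
            expected = logsumexp(branches)
            got = basic_site_marginal_loglik(params, w_all, data, Xo, Xc, Xk, i)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_psi_one_degenerates_to_conditional(self):
        y = np.array([[1, 1]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y)
        params.beta = np.r_[50.0, np.zeros(15)]
        Xo = np.zeros_like(Xo)
        marg = basic_site_marginal_loglik(params, w_all, data, Xo, Xc, Xk, 0)
        cond = basic_site_loglik(params, w_all, data, Xo, Xc, Xk, 0, 1)
        assert marg == pytest.approx(cond, abs=1e-10)

    def test_binary_logliks_nonpositive(self):
        y = np.array([[1, 0], [0, 1]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y)
        for i in range(2):
            assert basic_site_marginal_loglik(
                params, w_all, data, Xo, Xc, Xk, i) <= 0.0


class TestRNLikelihood:
    def _setup(self, y, mode="pooled", seed=6, N_max=200):
        rng = np.random.default_rng(seed)
        S = y.shape[0]
        X_occ, X_chev, X_cam = _toy_design(S, rng)
        k = np.array([1, 1]) if mode == "pooled" else np.array([1, 41])
        data = DetectionData(mode=mode, y=y, k=k)
        params = RNParams(beta=0.2 * rng.standard_normal(16),
                          alpha=0.2 * rng.standard_normal(7),
                          phi=0.2 * rng.standard_normal(5), N_max=N_max)
        w_all = (np.ones(15), np.ones(6), np.ones(4))
        return params, w_all, data, X_occ, X_chev, X_cam

    def test_empty_site_at_tiny_lambda(self):
        y = np.array([[0, 0]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y)
        params.beta = np.r_[-30.0, np.zeros(15)]
        got = rn_site_marginal_loglik(params, w_all, data,
                                      np.zeros_like(Xo), Xc, Xk, 0)
        assert got == pytest.approx(0.0, abs=1e-8)

    def test_truncation_convergence(self):
        y = np.array([[1, 1], [0, 1]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y, N_max=200)
        lo = [rn_site_marginal_loglik(params, w_all, data, Xo, Xc, Xk, i)
              for i in range(2)]
        params.N_max = 2000
        hi = [rn_site_marginal_loglik(params, w_all, data, Xo, Xc, Xk, i)
              for i in range(2)]
        np.testing.assert_allclose(lo, hi, atol=1e-10)

    def test_small_nmax_warns(self):
        y = np.array([[0, 0]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y)
        params.beta = np.r_[2.5, np.zeros(15)]
        params.N_max = 5
        with pytest.warns(RuntimeWarning, match="tail mass"):
            rn_site_marginal_loglik(params, w_all, data,
                                    np.zeros_like(Xo), Xc, Xk, 0)

    def test_perfect_detection_reduces_to_poisson_tail(self):
        # with r=1 both gears detect iff N >= 1, so y=(1,1) has
        # probability P(N >= 1)
        y = np.array([[1, 1]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y)
        params.beta = np.r_[0.4, np.zeros(15)]
        params.alpha = np.r_[40.0, np.zeros(6)]
        params.phi = np.r_[40.0, np.zeros(4)]
        Z = np.zeros_like
        got = rn_site_marginal_loglik(params, w_all, data, Z(Xo), Z(Xc), Z(Xk), 0)
        lam = math.exp(0.4)
        assert got == pytest.approx(math.log(-math.expm1(-lam)), abs=1e-9)

    def test_matches_exhaustive_enumeration(self):
        """Marginal equals the direct sum over the latent abundance."""
        y = np.array([[1, 0], [0, 1], [1, 1]])
        params, w_all, data, Xo, Xc, Xk = self._setup(y)
        r1 = detection_prob_chevron(params.alpha, w_all[1], Xc)
        r2 = detection_prob_camera(params.phi, w_all[2], Xk)
        lam = np.exp(params.beta[0] + Xo @ params.beta[1:])
        for i in range(3):
            total = 0.0
            for n in range(201):
                p1 = 1 - (1 - r1[i]) ** n
                p2 = 1 - (1 - r2[i]) ** n
                lik1 = p1 if y[i, 0] else 1 - p1
                lik2 = p2 if y[i, 1] else 1 - p2
                total += poisson.pmf(n, lam[i]) * lik1 * lik2
            got = rn_site_marginal_loglik(params, w_all, data, Xo, Xc, Xk, i)
            assert got == pytest.approx(math.log(total), abs=1e-10)

    def test_poisson_thinning_limit(self):
        """For small r at fixed lambda*r, the RN marginal approaches the
        basic-model marginal with psi=1 and p = 1-exp(-lambda*r)."""
        y_cases = [np.array([[0, 0]]), np.array([[1, 0]]),
                   np.array([[0, 1]]), np.array([[1, 1]])]
        lam, c1, c2 = 40.0, 0.4, 0.75   # lambda*r held at c
        for y in y_cases:
            params, w_all, data, Xo, Xc, Xk = self._setup(y, N_max=400)
            Z = np.zeros_like
            params.beta = np.r_[math.log(lam), np.zeros(15)]
            params.alpha = np.r_[float(logit_scalar(c1 / lam)), np.zeros(6)]
            params.phi = np.r_[float(logit_scalar(c2 / lam)), np.zeros(4)]
            got = rn_site_marginal_loglik(params, w_all, data, Z(Xo), Z(Xc), Z(Xk), 0)
            p1 = -math.expm1(-c1)
            p2 = -math.expm1(-c2)
            lik1 = p1 if y[0, 0] else 1 - p1
            lik2 = p2 if y[0, 1] else 1 - p2
            assert got == pytest.approx(math.log(lik1 * lik2), abs=2e-2)


def logit_scalar(p):
    return math.log(p) - math.log1p(-p)
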