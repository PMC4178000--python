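import math

import numpy as np
import pytest
from scipy.stats import binom, poisson

from gearocc import ModelSpec, chisq_stat, history_cell_probs, parametric_bootstrap_gof
from gearocc.data import DetectionData, DesignMatrices
from gearocc.gof import camera_bins, point_estimates
from gearocc.models import logit

from conftest import make_samples


def _design(S, seed=0):
    rng = np.random.default_rng(seed)
    return DesignMatrices(X_occ=0.3 * rng.standard_normal((S, 15)),
                          X_chev=0.3 * rng.standard_normal((S, 6)),
                          X_cam=0.3 * rng.standard_normal((S, 4)), scaling={})


def _estimates(psi=None, p1=None, p2=None, lam=None):
    b0 = logit(psi) if psi is not None else math.log(lam)
    return {"beta": np.r_[float(b0), np.zeros(15)],
            "alpha": np.r_[float(logit(p1)), np.zeros(6)],
            "phi": np.r_[float(logit(p2)), np.zeros(4)]}


class TestHistoryCellProbs:
    def test_certain_occupancy_half_detection(self):
        est = _estimates(psi=1 - 1e-12, p1=0.5, p2=0.5)
        design = DesignMatrices(X_occ=np.zeros((2, 15)), X_chev=np.zeros((2, 6)),
                                X_cam=np.zeros((2, 4)), scaling={})
        probs = history_cell_probs(est, ModelSpec(), design)
        np.testing.assert_allclose(probs, 0.25, atol=1e-9)

    def test_zero_occupancy_all_mass_on_empty_history(self):
        est = _estimates(psi=1e-14, p1=0.5, p2=0.5)
        design = _design(3)
        probs = history_cell_probs(est, ModelSpec(), design)
        np.testing.assert_allclose(probs[:, 0], 1.0, atol=1e-9)

    def test_rows_sum_to_one(self):
        est = _estimates(psi=0.4, p1=0.3, p2=0.7)
        for spec in (ModelSpec(), ModelSpec(camera_mode="disaggregated"),
                     ModelSpec(family="royle_nichols", N_max=60),
                     ModelSpec(family="royle_nichols",
                               camera_mode="disaggregated", N_max=60)):
            est2 = dict(est)
            if spec.family == "royle_nichols":
                est2 = _estimates(lam=0.8, p1=0.3, p2=0.2)
            probs = history_cell_probs(est2, spec, _design(4))
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_exhaustive_enumeration_basic_pooled(self):
        est = _estimates(psi=0.37, p1=0.22, p2=0.64)
        design = _design(3, seed=5)
        probs = history_cell_probs(est, ModelSpec(), design)
        from gearocc.models import inv_logit
        psi = inv_logit(est["beta"][0] + design.X_occ @ est["beta"][1:])
        p1 = inv_logit(est["alpha"][0] + design.X_chev @ est["alpha"][1:])
        p2 = inv_logit(est["phi"][0] + design.X_cam @ est["phi"][1:])
        for i in range(3):
            for y1 in (0, 1):
                for y2 in (0, 1):
                    expected = psi[i] * (p1[i] ** y1 * (1 - p1[i]) ** (1 - y1)
                                         * p2[i] ** y2 * (1 - p2[i]) ** (1 - y2))
                    if y1 == 0 and y2 == 0:
                        expected += 1 - psi[i]
                    assert probs[i, y1 * 2 + y2] == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_enumeration_rn(self):
        est = _estimates(lam=1.3, p1=0.4, p2=0.25)
        spec = ModelSpec(family="royle_nichols", N_max=150)
        design = _design(2, seed=6)
        probs = history_cell_probs(est, spec, design)
        from gearocc.models import inv_logit
        lam = np.exp(est["beta"][0] + design.X_occ @ est["beta"][1:])
        r1 = inv_logit(est["alpha"][0] + design.X_chev @ est["alpha"][1:])
        r2 = inv_logit(est["phi"][0] + design.X_cam @ est["phi"][1:])
        for i in range(2):
            for y1 in (0, 1):
                for y2 in (0, 1):
                    total = 0.0
                    for n in range(151):
                        pd1 = 1 - (1 - r1[i]) ** n
                        pd2 = 1 - (1 - r2[i]) ** n
                        total += (poisson.pmf(n, lam[i])
                                  * (pd1 if y1 else 1 - pd1)
                                  * (pd2 if y2 else 1 - pd2))
                    assert probs[i, y1 * 2 + y2] == pytest.approx(total, rel=1e-8)


class TestChisqStat:
    def test_zero_when_data_at_expectation(self):
        # expected probabilities put all mass on the observed histories
        y = np.array([[1, 1], [0, 0]])
        data = DetectionData(mode="pooled", y=y, k=np.array([1, 1]))
        probs = np.array([[0.0, 0.0, 0.0, 1.0], [1.0, 0.0, 0.0, 0.0]])
        assert chisq_stat(data, probs) == pytest.approx(0.0)

    def test_hand_computed_two_site_example(self):
        y = np.array([[1, 0], [0, 1]])
        data = DetectionData(mode="pooled", y=y, k=np.array([1, 1]))
        probs = np.array([[0.4, 0.1, 0.3, 0.2], [0.25, 0.25, 0.25, 0.25]])
        # site 0 observed cell (1,0) -> index 2; site 1 observed (0,1) -> 1
        expected = ((0 - .4) ** 2 / .4 + (0 - .1) ** 2 / .1 + (1 - .3) ** 2 / .3
                    + (0 - .2) ** 2 / .2
                    + 3 * (0 - .25) ** 2 / .25 + (1 - .25) ** 2 / .25)
        assert chisq_stat(data, probs) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=(6, 2))
        data = DetectionData(mode="pooled", y=y, k=np.array([1, 1]))
        probs = rng.dirichlet(np.ones(4), size=6)
        stat = chisq_stat(data, probs)
        perm = rng.permutation(6)
        data_p = DetectionData(mode="pooled", y=y[perm], k=np.array([1, 1]))
        assert chisq_stat(data_p, probs[perm]) == pytest.approx(stat, abs=1e-12)

    def test_disaggregated_bins_have_min_mass(self):
        est = _estimates(psi=0.5, p1=0.4, p2=0.1)
        spec = ModelSpec(camera_mode="disaggregated")
        design = _design(30, seed=8)
        probs = history_cell_probs(est, spec, design)
        bins = camera_bins(probs, "disaggregated", min_expected=2.0)
        grid = probs.reshape(-1, 2, 42).sum(axis=(0, 1))
        masses = [grid[b].sum() for b in bins]
        assert all(m >= 2.0 * 2 for m in masses[:-1])
        assert sorted(np.concatenate(bins)) == list(range(42))


class TestParametricBootstrap:
    def test_gof_p_is_exceedance_proportion(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=(25, 2))
        data = DetectionData(mode="pooled", y=y, k=np.array([1, 1]))
        est = _estimates(psi=0.5, p1=0.4, p2=0.6)
        res = parametric_bootstrap_gof(est, data, _design(25), n_boot=60,
                                       seed=4, model_spec=ModelSpec())
        assert res.gof_p == pytest.approx(
            np.mean(res.boot_stats >= res.observed_stat))
        assert 0.0 <= res.gof_p <= 1.0
        assert res.n_boot == len(res.boot_stats) == 60

    def test_zero_bootstrap_errors(self):
        data = DetectionData(mode="pooled", y=np.zeros((3, 2), int),
                             k=np.array([1, 1]))
        with pytest.raises(ValueError):
            parametric_bootstrap_gof(_estimates(psi=.5, p1=.5, p2=.5), data,
                                     _design(3), n_boot=0, model_spec=ModelSpec())

    def test_point_estimates_from_samples(self):
        samples = make_samples(beta=np.r_[0.3, np.ones(15)], w_occ=0.0)
        est = point_estimates(samples)
        assert est["beta"][0] == pytest.approx(0.3)
        np.testing.assert_allclose(est["beta"][1:], 0.0)

    def test_result_json_round_trip(self, tmp_path):
        from gearocc.gof import GofResult
        res = GofResult(observed_stat=1.5, boot_stats=np.array([1.0, 2.0]),
                        gof_p=0.5, n_boot=2, seed=7)
        res.to_json(tmp_path / "g.json")
        back = GofResult.from_json(tmp_path / "g.json")
        assert back.gof_p == 0.5
        np.testing.assert_allclose(back.boot_stats, res.boot_stats)
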