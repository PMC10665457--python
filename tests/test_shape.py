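"""Posterior-shape analysis: descriptive mixture fitting, disambiguation,
cluster comparison and peak-error regression."""

import numpy as np
import pandas as pd
import pytest

from motionbayes import shape as sh
from motionbayes.circular import DirectionDistribution, circdist


def make_pairs(rng, spec):
    """Clean peak pairs from a list of (mu_x, mu_y, kappa, n) clusters."""
    xs, ys = [], []
    for mu_x, mu_y, kappa, n in spec:
        xs.append(np.mod(mu_x + np.rad2deg(rng.vonmises(0, kappa, n)), 360))
        ys.append(np.mod(mu_y + np.rad2deg(rng.vonmises(0, kappa, n)), 360))
    return pd.DataFrame(
        {"mu_large": np.concatenate(xs), "mu_small": np.concatenate(ys)}
    )


class TestDescriptiveMixtureFit:
    def test_self_consistency_recovery(self, grid):
        """Parameters of an exactly-representable posterior are recovered."""
        true = sh.DescriptiveMixture(0.1, 0.7, 0.0, 20.0, 180.0, 10.0)
        fit = sh.fit_descriptive_mixture(true.on_grid(grid), n_restarts=60, seed=0)
        # undo possible label swap
        if abs(circdist(fit.mu1, 0.0)) > abs(circdist(fit.mu2, 0.0)):
            alpha = 1 - fit.alpha
            mu1, k1, mu2, k2 = fit.mu2, fit.kappa2, fit.mu1, fit.kappa1
        else:
            alpha, mu1, k1, mu2, k2 = fit.alpha, fit.mu1, fit.kappa1, fit.mu2, fit.kappa2
        assert fit.lapse_weight == pytest.approx(0.1, abs=0.02)
        assert alpha == pytest.approx(0.7, abs=0.05)
        assert abs(circdist(mu1, 0.0)) < 2.0
        assert k1 == pytest.approx(20.0, rel=0.15)
        assert abs(circdist(mu2, 180.0)) < 2.0
        assert k2 == pytest.approx(10.0, rel=0.15)

    def test_uniform_posterior_fits_with_tiny_jsd(self, grid):
        u = DirectionDistribution.uniform(grid)
        fit = sh.fit_descriptive_mixture(u, n_restarts=10, seed=1)
        assert sh._jsd_mass(u.mass, fit.on_grid(grid).mass) < 1e-3

    def test_symmetric_bimodal_recovers_both_modes(self, grid):
        sym = sh.DescriptiveMixture(0.0, 0.5, 20.0, 10.0, 200.0, 10.0).on_grid(grid)
        fit = sh.fit_descriptive_mixture(sym, n_restarts=30, seed=2)
        modes = sorted([round(fit.mu1), round(fit.mu2) % 360])
        assert modes == [20, 200]
        assert fit.alpha == pytest.approx(0.5, abs=0.01)

    def test_best_of_restarts_never_worse_with_more_restarts(self, grid):
        target = sh.DescriptiveMixture(0.2, 0.6, 50.0, 5.0, 210.0, 2.0).on_grid(grid)
        f_few = sh.fit_descriptive_mixture(target, n_restarts=2, seed=3, early_stop_jsd=0.0)
        f_many = sh.fit_descriptive_mixture(target, n_restarts=30, seed=3, early_stop_jsd=0.0)
        assert f_many.jsd <= f_few.jsd + 1e-15

    def test_gradient_matches_finite_differences(self, grid, rng):
        target = sh.DescriptiveMixture(0.1, 0.7, 0.0, 20.0, 180.0, 10.0).on_grid(grid).mass
        x = np.array([0.2, 0.5, 123.0, 4.0, 301.0, 9.0])
        _, g = sh._jsd_objective_and_grad(x, target, grid)
        for i in range(6):
            e = np.zeros(6)
            e[i] = 1e-6
            fd = (
                sh._jsd_objective_and_grad(x + e, target, grid)[0]
                - sh._jsd_objective_and_grad(x - e, target, grid)[0]
            ) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-10)


class TestDisambiguate:
    def test_weight_dominant_component_is_larger(self):
        m = sh.DescriptiveMixture(0.0, 0.9, 10.0, 5.0, 200.0, 5.0)
        pair = sh.disambiguate(m, true_direction=0.0)
        assert pair.mu_large == 10.0
        assert pair.mu_small == 200.0

    def test_equal_heights_fall_back_to_proximity(self):
        m = sh.DescriptiveMixture(0.0, 0.5, 90.0, 5.0, 270.0, 5.0)
        pair = sh.disambiguate(m, true_direction=80.0)
        assert pair.mu_large == 90.0  # nearer the truth on an exact tie

    def test_conventions_agree_for_separated_unequal_components(self, rng):
        agree = 0
        total = 0
        for _ in range(100):
            alpha = rng.uniform(0.6, 0.95)
            mu1 = rng.uniform(0, 360)
            mu2 = np.mod(mu1 + rng.uniform(120, 240), 360)
            m = sh.DescriptiveMixture(0.05, alpha, mu1, 8.0, mu2, 8.0)
            pair = sh.disambiguate(m, true_direction=mu1)
            total += 1
            agree += pair.conventions_agree
        assert agree == total


class TestWAIC:
    def test_matches_arviz(self, rng):
        """Hand-rolled WAIC against the reference implementation."""
        az = pytest.importorskip("arviz")
        ll = rng.normal(-1.0, 0.3, size=(400, 50))
        waic, p_eff = sh.compute_waic(ll)
        idata = az.from_dict(log_likelihood={"y": ll[None, :, :]})
        ref = az.waic(idata, scale="deviance")
        # agreement up to the variance ddof convention
        assert waic == pytest.approx(ref.elpd_waic, rel=1e-3)
        assert p_eff == pytest.approx(ref.p_waic, rel=5e-3)


class TestClusterComparison:
    def test_single_cluster_preferred_with_margin(self, rng):
        pairs = make_pairs(rng, [(0.0, 0.0, 8.0, 300)])
        res = sh.cluster_peak_pairs(
            pairs, seed=0, method="waic", n_steps=800, n_burn=300
        )
        tab = res["table"].set_index("n_clusters")
        assert res["preferred_clusters"] == 1
        assert tab.loc[2, "waic"] - tab.loc[1, "waic"] > 10 or res["preferred_model"] == 1

    def test_two_clusters_recovered_with_mixing_fraction(self, rng):
        pairs = make_pairs(rng, [(0.0, 0.0, 8.0, 150), (0.0, 180.0, 8.0, 150)])
        res = sh.cluster_peak_pairs(
            pairs, seed=0, method="waic", n_steps=800, n_burn=300
        )
        assert res["preferred_clusters"] == 2
        weights = sorted(w for _, _, w in res["cluster_locations"])
        assert weights[-1] == pytest.approx(0.5, abs=0.05)
        tab = res["table"].set_index("n_clusters")
        # third cluster brings no significant improvement on 2-cluster data
        assert tab.loc[3, "waic"] > tab.loc[2, "waic"] - 2.0

    def test_em_bic_fallback_agrees(self, rng):
        pairs = make_pairs(rng, [(0.0, 0.0, 8.0, 150), (0.0, 180.0, 8.0, 150)])
        res = sh.cluster_peak_pairs(pairs, seed=0, method="bic")
        assert res["preferred_clusters"] == 2

    def test_too_few_pairs_rejected(self, rng):
        pairs = make_pairs(rng, [(0.0, 0.0, 8.0, 20)])
        with pytest.raises(ValueError):
            sh.cluster_peak_pairs(pairs)

    def test_distinct_cluster_merging(self):
        # two co-located components + one opposite: merged to 2 distinct
        params = np.array(
            [0.0, 0.0, np.log(50.0), np.log(50.0),
             0.05, 0.05, np.log(3.0), np.log(3.0),
             0.0, np.pi, np.log(8.0), np.log(8.0),
             1.0, 0.5, 0.5]
        )
        merged = sh._distinct_clusters(params, 3, background=True)
        assert len(merged) == 2


class TestPeakErrorRegression:
    def test_constructed_positive_relationship(self, rng):
        n = 500
        peak1 = rng.uniform(-40, 40, n)
        peak2 = rng.uniform(-40, 40, n)
        err = 10 * np.sin(np.pi * peak1 / 90) + 5 * np.sin(np.pi * peak2 / 90) + rng.normal(0, 3, n)
        res = sh.peak_error_regression(
            peak_near_true=np.mod(peak1, 360),
            peak_near_opposite=np.mod(180 + peak2, 360),
            true_direction=np.zeros(n),
            behavioral_errors=err,
            n_permutations=200,
            seed=0,
        )
        assert res["slope_first_peak"] == pytest.approx(10.0, rel=0.15)
        assert res["slope_second_peak"] == pytest.approx(5.0, rel=0.3)
        assert res["p_first_peak"] < 0.01 and res["p_second_peak"] < 0.01

    def test_too_few_selected_trials_refused(self, rng):
        with pytest.raises(ValueError, match="bimodal-selected"):
            sh.peak_error_regression(
                peak_near_true=np.zeros(30),
                peak_near_opposite=np.zeros(30),  # nothing near opposite
                true_direction=np.zeros(30),
                behavioral_errors=rng.normal(0, 5, 30),
            )
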