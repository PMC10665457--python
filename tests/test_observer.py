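"""Bayesian observer: measurement sampling, likelihoods, analytic posterior
mixture and readouts."""

import warnings

import numpy as np
import pytest

from motionbayes.circular import (
    circdist,
    circular_mean,
    ml_kappa,
    sigma_to_kappa,
    vm_pdf,
)
from motionbayes.observer import (
    Measurement,
    ObserverParams,
    combined_posterior,
    combined_posterior_arrays,
    map_closed_form,
    map_distribution_approx,
    map_readout,
    orientation_likelihood,
    sample_measurements,
    velocity_likelihood,
    velocity_only_readout,
)


class TestTypes:
    def test_measurement_range_enforced(self):
        with pytest.raises(ValueError):
            Measurement(x_v=-1.0, x_o=10.0)
        with pytest.raises(ValueError):
            Measurement(x_v=10.0, x_o=200.0)

    def test_negative_precision_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(-1.0, 2.0)

    def test_params_sigma_round_trip(self):
        p = ObserverParams.from_sigmas(10.0, 20.0)
        assert p.sigma_v == pytest.approx(10.0, rel=1e-6)
        assert p.sigma_o == pytest.approx(20.0, rel=1e-6)


class TestSampling:
    def test_high_precision_measurement_matches_stimulus(self, rng):
        m = sample_measurements(137.0, ObserverParams(1e6, 1e6), rng)
        assert abs(circdist(m.x_v, 137.0)) < 0.5

    def test_orientation_always_in_half_circle(self, rng):
        for s in rng.uniform(0, 360, 50):
            m = sample_measurements(s, ObserverParams(1.0, 1.0), rng)
            assert 0 <= m.x_o < 180

    def test_velocity_circular_mean_recovers_stimulus(self, rng):
        draws = [
            sample_measurements(90.0, ObserverParams(5.0, 5.0), rng).x_v
            for _ in range(10_000)
        ]
        assert abs(circdist(circular_mean(np.array(draws)), 90.0)) < 2.0


class TestLikelihoods:
    def test_velocity_mode_and_pointwise_match(self, grid):
        like = velocity_likelihood(123.5, 4.0, grid)
        assert like.mode() == pytest.approx(123.5)
        expected = vm_pdf(grid.angles, 123.5, 4.0)
        np.testing.assert_allclose(like.mass, expected / expected.sum(), rtol=1e-9)

    def test_velocity_flat_at_zero_kappa(self, grid):
        like = velocity_likelihood(10.0, 0.0, grid)
        np.testing.assert_allclose(like.mass, 1.0 / grid.n, rtol=1e-9)

    def test_orientation_180_symmetry(self, grid):
        like = orientation_likelihood(30.0, 10.0, grid)
        np.testing.assert_allclose(like.mass, np.roll(like.mass, 360), atol=1e-15)
        # modes at x_O and x_O + 180
        top2 = np.sort(grid.angles[np.argsort(like.mass)[-2:]])
        assert list(top2) == [30.0, 210.0]

    def test_orientation_flat_at_zero_kappa(self, grid):
        like = orientation_likelihood(30.0, 0.0, grid)
        np.testing.assert_allclose(like.mass, 1.0 / grid.n, rtol=1e-9)


class TestCombinedPosterior:
    def test_matches_brute_force_product(self, grid, rng):
        """Analytic mixture equals the normalized likelihood product."""
        for _ in range(100):
            x_v, x_o = rng.uniform(0, 360), rng.uniform(0, 180)
            k_v, k_o = rng.lognormal(1, 1), rng.lognormal(1, 1)
            post = combined_posterior(
                Measurement(x_v, x_o), ObserverParams(k_v, k_o)
            ).on_grid(grid)
            brute = vm_pdf(grid.angles, x_v, k_v) * (
                vm_pdf(grid.angles, x_o, k_o) + vm_pdf(grid.angles, x_o + 180, k_o)
            )
            brute /= brute.sum()
            assert np.abs(post.mass - brute).max() < 1e-8

    def test_precise_velocity_suppresses_second_component(self):
        post = combined_posterior(Measurement(10.0, 10.0), ObserverParams(50.0, 5.0))
        assert post.w_b < 1e-3

    def test_flat_velocity_gives_equal_peaks(self, grid):
        post = combined_posterior(Measurement(0.0, 40.0), ObserverParams(1e-9, 10.0))
        assert post.w_a == pytest.approx(0.5, abs=1e-6)
        assert {round(post.theta_a), round(post.theta_b)} == {40, 220}

    def test_both_kappas_zero_near_uniform(self, grid):
        post = combined_posterior(Measurement(0.0, 0.0), ObserverParams(0.0, 0.0))
        assert post.w_a == pytest.approx(0.5, abs=1e-9)
        on_grid = post.on_grid(grid)
        np.testing.assert_allclose(on_grid.mass, 1.0 / grid.n, rtol=1e-9)

    def test_velocity_shift_by_180_translates_posterior(self):
        # L_O is 180-periodic, so shifting x_V by 180 shifts the whole
        # posterior by 180: same weights, components translated
        p1 = combined_posterior(Measurement(20.0, 30.0), ObserverParams(3.0, 6.0))
        p2 = combined_posterior(Measurement(200.0, 30.0), ObserverParams(3.0, 6.0))
        assert p1.w_a == pytest.approx(p2.w_a, rel=1e-9)
        assert abs(circdist(p2.theta_a, p1.theta_a + 180.0)) < 1e-6
        assert abs(circdist(p2.theta_b, p1.theta_b + 180.0)) < 1e-6

    def test_component_a_is_nearer_velocity_measurement(self, rng):
        x_v = rng.uniform(0, 360, 200)
        x_o = rng.uniform(0, 180, 200)
        w_a, w_b, th_a, th_b, _, _ = combined_posterior_arrays(x_v, x_o, 2.0, 4.0)
        assert np.all(np.abs(circdist(th_a, x_v)) <= np.abs(circdist(th_b, x_v)) + 1e-9)

    def test_combined_entropy_below_velocity_only(self, grid, rng):
        """Orientation information always reduces average uncertainty."""
        from motionbayes.circular import DirectionDistribution

        k_v, k_o = sigma_to_kappa(20.0), sigma_to_kappa(30.0)
        vel_entropy = DirectionDistribution.von_mises(0.0, k_v, grid).entropy_bits()
        ents = []
        for _ in range(300):
            m = sample_measurements(0.0, ObserverParams(k_v, k_o), rng)
            ents.append(combined_posterior(m, ObserverParams(k_v, k_o)).entropy_bits(grid))
        assert np.mean(ents) < vel_entropy


class TestReadouts:
    def test_unimodal_map_is_mode(self):
        post = combined_posterior(Measurement(90.0, 90.0), ObserverParams(30.0, 30.0))
        assert abs(circdist(map_readout(post), 90.0)) <= 0.5

    def test_symmetric_bimodal_tie_break_smaller_angle(self, grid):
        # flat velocity, orientation at exactly 40: peaks at 40 and 220,
        # exactly equal; the smaller canonical angle must win
        post = combined_posterior(Measurement(0.0, 40.0), ObserverParams(0.0, 10.0))
        assert map_readout(post, grid) == 40.0

    def test_matches_closed_form_in_low_noise_regime(self, rng):
        """Grid argmax vs the analytic approximation, sigma_V=sigma_O=10 deg."""
        params = ObserverParams.from_sigmas(10.0, 10.0)
        for _ in range(1000):
            m = sample_measurements(rng.uniform(0, 360), params, rng)
            post = combined_posterior(m, params)
            approx = map_closed_form(m.x_v, m.x_o, params.kappa_v, params.kappa_o)
            assert abs(circdist(map_readout(post), approx)) < 1.0

    def test_velocity_only_identity_and_independence(self):
        assert velocity_only_readout(Measurement(123.0, 5.0)) == 123.0
        assert velocity_only_readout(Measurement(123.0, 170.0)) == 123.0

    def test_velocity_only_distribution_recovers_kappa(self, rng):
        k_v = 10.0
        draws = np.array(
            [
                sample_measurements(45.0, ObserverParams(k_v, 1.0), rng).x_v
                for _ in range(10_000)
            ]
        )
        assert ml_kappa(draws) == pytest.approx(k_v, rel=0.10)


class TestMapDistributionApprox:
    def test_zero_orientation_precision(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu, kappa = map_distribution_approx(30.0, ObserverParams(8.0, 0.0))
        assert mu == 30.0
        assert kappa == 8.0

    def test_aligned_measurements_give_velocity_estimate(self):
        # when x_V and x_O agree, the closed-form shift term vanishes
        assert map_closed_form(50.0, 50.0, 5.0, 5.0) == pytest.approx(50.0, abs=1e-9)

    def test_warns_when_second_component_non_negligible(self):
        with pytest.warns(UserWarning, match="approximation"):
            map_distribution_approx(0.0, ObserverParams.from_sigmas(60.0, 10.0))

    def test_simulated_concentration_matches_sum(self, rng):
        """ML-fitted concentration of MAP estimates ~ kappa_O + kappa_V."""
        from motionbayes.simulate import simulate_cell

        cell = simulate_cell(10.0, 10.0, 5000, 7)
        k_sum = 2 * sigma_to_kappa(10.0)
        assert ml_kappa(cell.map_responses) == pytest.approx(k_sum, rel=0.10)
        assert abs(circdist(circular_mean(cell.map_responses), 0.0)) < 1.0
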