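"""Probabilistic decoder: basis, tuning fit, structured noise, decoding and
cross-validation."""

import numpy as np
import pytest

from motionbayes import decoder as dec
from motionbayes import synth
from motionbayes.circular import DirectionGrid, circ_corr, circdist


class TestBasis:
    def test_peak_at_preferred_direction(self):
        g = dec.basis_response(0.0)[0]
        assert g[0] == pytest.approx(1.0)

    def test_zero_beyond_90_degrees(self):
        g = dec.basis_response(np.arange(0, 360, 1.0))
        phi = 360.0 * np.arange(8) / 8
        for k in range(8):
            far = np.abs(circdist(np.arange(0, 360, 1.0), phi[k])) >= 90.0
            # cos(90 deg) is ~6e-17 in floating point; the fifth power is
            # far below any meaningful response
            assert np.all(g[far, k] < 1e-30)

    def test_positive_coverage_everywhere(self, grid):
        g = dec.basis_response(grid.angles)
        assert np.all(g.sum(axis=1) > 0)

    def test_values_in_unit_interval(self):
        g = dec.basis_response(np.arange(0, 360, 0.5))
        assert g.min() >= 0.0 and g.max() <= 1.0


class TestFitTuning:
    def test_noiseless_exact_recovery(self, rng):
        W = rng.gamma(2.0, 1.0, size=(30, 8))
        s = rng.uniform(0, 360, 100)
        B = dec.basis_response(s) @ W.T
        model, resid = dec.fit_tuning(B, s)
        np.testing.assert_allclose(model.W, W, atol=1e-8)
        assert np.abs(resid).max() < 1e-8

    def test_rank_deficient_design_rejected(self, rng):
        B = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="rank"):
            dec.fit_tuning(B, np.full(20, 45.0))

    def test_permuted_labels_destroy_fit(self, small_voxel_dataset, rng):
        ds = small_voxel_dataset
        model, resid = dec.fit_tuning(ds.B, ds.s)
        perm_model, perm_resid = dec.fit_tuning(ds.B, rng.permutation(ds.s))
        var_explained = 1 - resid.var() / ds.B.var()
        var_perm = 1 - perm_resid.var() / ds.B.var()
        # permuted labels retain only the ~K/n overfitting share
        assert var_perm < 8.5 / len(ds.s) * 1.5
        assert var_explained > 1.5 * var_perm


class TestFitNoise:
    def test_full_shrinkage_returns_sample_covariance(self, rng):
        R = rng.standard_normal((200, 20))
        W = rng.gamma(2.0, 1.0, (20, 8))
        noise = dec.fit_noise(R, W, lambda_shrink=1.0, lambda_var=0.0)
        np.testing.assert_allclose(noise.omega, R.T @ R / 200, atol=1e-10)

    def test_structured_only_diagonal_when_uncorrelated(self, rng):
        R = rng.standard_normal((500, 15))
        W = rng.gamma(2.0, 1.0, (15, 8))
        noise = dec.fit_noise(R, W, lambda_shrink=0.0, lambda_var=0.0, method="moment")
        off = noise.omega - np.diag(np.diag(noise.omega))
        # iid residuals: fitted rho and sigma2 near zero -> near-diagonal
        assert np.abs(off).max() < 0.2 * np.diag(noise.omega).min()

    def test_parameter_recovery_from_structured_noise(self, rng):
        truth = synth.make_truth(n_voxels=40, rho=0.2, sigma2=0.05, seed=0)
        chol = np.linalg.cholesky(truth.covariance())
        R = rng.standard_normal((2000, 40)) @ chol.T
        noise = dec.fit_noise(R, truth.W, lambda_shrink=0.0, lambda_var=0.0, method="moment")
        assert noise.rho == pytest.approx(0.2, rel=0.2)
        # tau' fixed at residual SDs absorbs part of the tuning-shared
        # variance, so sigma2 recovers with a known downward bias
        assert noise.sigma2 == pytest.approx(0.05, rel=0.5)

    def test_too_few_voxels_rejected(self, rng):
        with pytest.raises(ValueError):
            dec.fit_noise(rng.standard_normal((10, 1)), np.ones((1, 8)))

    def test_invalid_shrinkage_rejected(self, rng):
        with pytest.raises(ValueError):
            dec.fit_noise(rng.standard_normal((10, 3)), np.ones((3, 8)), lambda_shrink=1.5)


class TestDecodeTrial:
    def test_two_voxel_closed_form_oracle(self, grid):
        """Hand-computed Gaussian posterior for 2 voxels."""
        W = np.array([[1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        tuning = dec.TuningModel(W=W)
        omega = np.array([[0.3, 0.05], [0.05, 0.4]])
        noise = dec.NoiseModel(
            tau=np.sqrt(np.diag(omega)), rho=0.0, sigma2=0.0,
            lambda_shrink=0.0, lambda_var=0.0, omega=omega,
        )
        b = np.array([0.7, 0.1])
        res = dec.decode_trial(b, tuning, noise, grid)
        F = tuning.predict(grid.angles)
        inv = np.linalg.inv(omega)
        logp = np.array([-0.5 * (b - f) @ inv @ (b - f) for f in F])
        expected = np.exp(logp - logp.max())
        expected /= expected.sum()
        np.testing.assert_allclose(res.posterior.mass, expected, atol=1e-10)

    def test_mode_recovered_from_clean_pattern(self, grid, rng):
        truth = synth.make_truth(n_voxels=60, seed=1)
        tuning = dec.TuningModel(W=truth.W)
        omega = 1e-4 * np.eye(60)
        noise = dec.NoiseModel(
            tau=np.full(60, 1e-2), rho=0.0, sigma2=0.0,
            lambda_shrink=0.0, lambda_var=0.0, omega=omega,
        )
        s_star = 137.5
        b = tuning.predict(s_star)[0] + 1e-4 * rng.standard_normal(60)
        res = dec.decode_trial(b, tuning, noise, grid)
        assert abs(circdist(res.posterior.mode(), s_star)) <= grid.step

    def test_inflating_covariance_raises_entropy(self, grid, rng):
        truth = synth.make_truth(n_voxels=30, seed=2)
        tuning = dec.TuningModel(W=truth.W)
        omega = truth.covariance()
        b = tuning.predict(90.0)[0] + 0.3 * rng.standard_normal(30)
        ents = []
        for scale in (1.0, 4.0):
            noise = dec.NoiseModel(
                tau=truth.tau, rho=truth.rho, sigma2=truth.sigma2,
                lambda_shrink=0.0, lambda_var=0.0, omega=scale * omega,
            )
            ents.append(dec.decode_trial(b, tuning, noise, grid).uncertainty_bits)
        assert ents[1] > ents[0]

    def test_posterior_mass_normalized(self, grid, rng):
        truth = synth.make_truth(n_voxels=30, seed=3)
        tuning = dec.TuningModel(W=truth.W)
        noise = dec.NoiseModel(
            tau=truth.tau, rho=truth.rho, sigma2=truth.sigma2,
            lambda_shrink=0.0, lambda_var=0.0, omega=truth.covariance(),
        )
        res = dec.decode_trial(rng.standard_normal(30), tuning, noise, grid)
        assert res.posterior.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_wrong_voxel_count_rejected(self):
        tuning = dec.TuningModel(W=np.ones((5, 8)))
        noise = dec.NoiseModel(
            tau=np.ones(5), rho=0.0, sigma2=0.0,
            lambda_shrink=0.0, lambda_var=0.0, omega=np.eye(5),
        )
        with pytest.raises(ValueError):
            dec.decode_trial(np.ones(4), tuning, noise)


class TestCrossvalDecode:
    def test_single_run_rejected(self):
        design = synth.make_design(1, seed=0)
        truth = synth.make_truth(n_voxels=20, seed=0)
        ds = synth.sample_voxel_patterns(design, truth, seed=0)
        with pytest.raises(ValueError):
            dec.crossval_decode(ds, n_boot=1)

    def test_no_resampling_equals_direct_decode(self, small_voxel_dataset):
        """n_boot=1 uses the full training set: must equal a manual
        train/test split decode."""
        ds = small_voxel_dataset
        table = dec.crossval_decode(ds, n_boot=1, seed=0, select_lambdas=False)
        run0 = ds.run_id == np.unique(ds.run_id)[0]
        tuning, resid = dec.fit_tuning(ds.B[~run0], ds.s[~run0])
        noise = dec.fit_noise(resid, tuning.W, 0.2, 0.5)
        manual = dec.decode_trials(ds.B[run0], tuning, noise)
        grid = DirectionGrid()
        z = manual @ np.exp(1j * grid.radians)
        manual_dirs = np.mod(np.rad2deg(np.angle(z)), 360.0)
        got = table.loc[table.run == np.unique(ds.run_id)[0], "s_decoded"].to_numpy()
        np.testing.assert_allclose(got, manual_dirs, atol=1e-9)

    def test_recovery_and_calibration(self, small_voxel_dataset):
        """Decoded directions track the truth; uncertainty tracks error."""
        from scipy.stats import spearmanr

        table = dec.crossval_decode(small_voxel_dataset, n_boot=5, seed=0)
        r = circ_corr(table.s_true.to_numpy(), table.s_decoded.to_numpy())
        # compact dataset (80 voxels, 6 runs); full-size recovery is
        # exercised in the acceptance suite
        assert r > 0.45
        err = np.abs(circdist(table.s_decoded, table.s_true))
        rho = spearmanr(table.entropy_bits, err)
        assert rho.statistic > 0

    def test_recovery_improves_with_snr(self):
        """Three-point SNR ladder: decoding monotonically improves."""
        rs = []
        for noise_scale in (0.9, 0.45, 0.15):
            design = synth.make_design(6, seed=1)
            truth = synth.make_truth(n_voxels=60, noise_scale=noise_scale, seed=2)
            ds = synth.sample_voxel_patterns(design, truth, seed=3)
            table = dec.crossval_decode(ds, n_boot=2, seed=4, select_lambdas=False)
            rs.append(circ_corr(table.s_true.to_numpy(), table.s_decoded.to_numpy()))
        assert rs[0] < rs[1] < rs[2]
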