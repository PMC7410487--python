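"""Decoders, reconstruction accuracy, phase-scrambled permutation nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modenc import decoding, encoding, synthetic
from modenc.auditory import grid_axes
from modenc.decoding import (
    fit_decoders,
    marginal_accuracy_profiles,
    permutation_null,
    phase_scramble,
    reconstruct_features,
    reconstruction_accuracy,
    run_decoding_cv,
)


class TestFitDecoders:
    def test_matches_intercept_ridge_oracle(self, rng):
        Y = rng.standard_normal((30, 5))
        S = rng.standard_normal((30, 3))
        lam = 2.5
        dec = fit_decoders(Y, S, np.array([lam]))
        # brute-force ridge with unpenalized intercept: centre, solve, shift
        Yc = Y - Y.mean(0)
        Sc = S - S.mean(0)
        coef = np.linalg.solve(Yc.T @ Yc + lam * np.eye(5), Yc.T @ Sc)
        bias = S.mean(0) - Y.mean(0) @ coef
        np.testing.assert_allclose(dec.coef, coef, atol=1e-8)
        np.testing.assert_allclose(dec.bias, bias, atol=1e-8)

    def test_constant_feature_gets_zero_weights_and_mean_bias(self, rng):
        Y = rng.standard_normal((25, 4))
        S = np.full((25, 1), 3.3)
        dec = fit_decoders(Y, S)
        np.testing.assert_allclose(dec.coef, 0.0, atol=1e-10)
        np.testing.assert_allclose(dec.bias, 3.3, atol=1e-10)

    def test_identity_feature_recovers_unit_weight(self, rng):
        Y = rng.standard_normal((60, 4))
        S = Y[:, [1]]
        dec = fit_decoders(Y, S, np.array([1e-6]))
        assert dec.coef[1, 0] == pytest.approx(1.0, abs=1e-4)
        assert np.max(np.abs(np.delete(dec.coef[:, 0], 1))) < 1e-4


class TestReconstruction:
    def test_zero_weights_predict_bias(self, rng):
        dec = fit_decoders(rng.standard_normal((20, 3)), np.full((20, 2), 1.5))
        out = reconstruct_features(dec, rng.standard_normal((7, 3)))
        np.testing.assert_allclose(out, 1.5, atol=1e-10)

    def test_row_permutation_equivariance(self, rng):
        dec = fit_decoders(rng.standard_normal((20, 3)), rng.standard_normal((20, 2)))
        y = rng.standard_normal((6, 3))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            reconstruct_features(dec, y[perm]), reconstruct_features(dec, y)[perm]
        )

    def test_perfect_prediction_gives_unit_accuracy(self, rng):
        axes = grid_axes("roi_decoding")
        s = rng.standard_normal((40, axes.n_features))
        idx = [np.arange(20), np.arange(20, 40)]
        grid = reconstruction_accuracy([s[:20], s[20:]], [s[:20], s[20:]], idx, 40, axes)
        np.testing.assert_allclose(grid.r, 1.0)

    def test_incomplete_fold_coverage_rejected(self, rng):
        axes = grid_axes("roi_decoding")
        s = rng.standard_normal((10, axes.n_features))
        with pytest.raises(ValueError, match="exactly once"):
            reconstruction_accuracy([s[:5]], [s[:5]], [np.arange(5)], 10, axes)

    def test_independent_prediction_accuracy_near_zero(self, rng):
        axes = grid_axes("roi_decoding")
        pred = rng.standard_normal((2000, axes.n_features))
        act = rng.standard_normal((2000, axes.n_features))
        grid = reconstruction_accuracy([pred], [act], [np.arange(2000)], 2000, axes)
        assert np.percentile(np.abs(grid.r), 95) < 0.05


class TestMarginalAccuracyProfiles:
    def test_uniform_grid_gives_constant_profiles(self):
        axes = grid_axes("encoding")
        grid = decoding.ReconstructionGrid(r=np.full(axes.n_features, 0.3), axes=axes)
        prof = marginal_accuracy_profiles(grid)
        for d in prof:
            np.testing.assert_allclose(prof[d].values, 0.3)
            assert prof[d].aggregation == "mean"

    def test_one_hot_grid_mean_counting(self):
        axes = grid_axes("encoding")
        g = np.zeros(axes.shape)
        g[2, 1, 4] = 1.0
        grid = decoding.ReconstructionGrid(r=axes.flatten(g), axes=axes)
        prof = marginal_accuracy_profiles(grid)
        np.testing.assert_allclose(prof["rate"].values[2], 1.0 / 48.0)
        assert np.all(prof["rate"].values[[0, 1, 3, 4, 5]] == 0)


class TestPhaseScramble:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_spectrum_preserved(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(rng.integers(3, 200))
        y = phase_scramble(x, rng)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(x)), np.abs(np.fft.rfft(y)), atol=1e-8
        )

    def test_constant_series_unchanged(self, rng):
        x = np.full(50, 2.5)
        np.testing.assert_allclose(phase_scramble(x, rng), x, atol=1e-10)

    def test_mean_preserved(self, rng):
        x = rng.standard_normal(101) + 3.0
        assert phase_scramble(x, rng).mean() == pytest.approx(x.mean())

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            phase_scramble(np.array([1.0, 2.0]), rng)


@pytest.fixture(scope="module")
def tuned_null():
    """Noiseless tuned cohort with a small phase-scrambled null."""
    s_raw = synthetic.surrogate_feature_matrix(4, 40, "roi_decoding", seed=2)
    s_sim = encoding.zscore_feature_matrix(decoding.hrf_convolve(s_raw))
    co = synthetic.make_cohort(1, 1, 130, noise_sd=0.0, seed=6)
    y = synthetic.simulate_voxels(s_sim, co.subjects[0], seed=13)
    return s_raw, y


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, tuned_null):
        s_raw, y = tuned_null
        a = permutation_null(s_raw, y, n_perm=5, seed=3)
        b = permutation_null(s_raw, y, n_perm=5, seed=3)
        np.testing.assert_array_equal(a.null.accuracies, b.null.accuracies)

    def test_represented_features_strongly_significant(self, tuned_null):
        s_raw, y = tuned_null
        grid = permutation_null(s_raw, y, n_perm=100, seed=3)
        # every feature has a tuned voxel and there is no noise: accuracies
        # must sit far above the scrambled null
        assert np.median(grid.z) > 3.0
        assert grid.p.min() == pytest.approx(1.0 / 101.0)
        assert np.all(grid.p <= 1.0) and np.all(grid.p > 0.0)
        np.testing.assert_allclose(grid.r_chance, grid.null.accuracies.mean(0))

    def test_rejects_convolved_input(self, tuned_null, roi_features_convolved):
        _, y = tuned_null
        with pytest.raises(ValueError, match="pre-convolution"):
            permutation_null(roi_features_convolved, y, n_perm=2)


class TestRunDecodingCV:
    def test_noiseless_cohort_reconstructs_all_features(
        self, roi_features_convolved, roi_features_standardized
    ):
        # narrow tuning keeps the true coefficient matrix well-conditioned,
        # so every feature has a dedicated voxel to decode from
        co = synthetic.make_cohort(1, 1, 130, bandwidth_young=0.3,
                                   bandwidth_old=0.3, noise_sd=0.0, seed=7)
        y = synthetic.simulate_voxels(roi_features_standardized, co.subjects[0], seed=0)
        grid = run_decoding_cv(roi_features_convolved, y)
        assert np.all(grid.r > 0.9)
        assert np.all((grid.r >= -1) & (grid.r <= 1))

    def test_rate_concentrated_cohort_peaks_at_concentrated_bins(
        self, roi_features_convolved, roi_features_standardized
    ):
        axes = roi_features_convolved.axes
        w = np.zeros(len(axes.rates))
        w[2] = 1.0                                  # all voxels prefer 5.7 Hz
        co = synthetic.make_cohort(1, 1, 300, rate_weights=w, noise_sd=1.0, seed=3)
        y = synthetic.simulate_voxels(roi_features_standardized, co.subjects[0], seed=5)
        prof = marginal_accuracy_profiles(run_decoding_cv(roi_features_convolved, y))
        assert np.argmax(prof["rate"].values) == 2
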