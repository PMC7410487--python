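"""Encoding models: ridge/GCV, identification, MTFs, maps, CV."""

import numpy as np
import pytest

from modenc import encoding, synthetic
from modenc.auditory import grid_axes
from modenc.encoding import (
    best_feature_map,
    cv_folds,
    default_lambda_grid,
    fit_encoding,
    group_map,
    identification_scores,
    map_correlation,
    marginal_mtf,
    predict_responses,
    ridge_gcv,
    run_encoding_cv,
    zscore_columns,
)


class TestZscore:
    def test_basic_column(self):
        z, stats = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(0), 1, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            z, stats = zscore_columns(np.ones((5, 2)))
        assert np.all(z == 0)
        assert len(stats["constant_columns"]) == 2

    def test_train_stats_applied_to_test(self, rng):
        train = rng.standard_normal((50, 3))
        test = rng.standard_normal((20, 3)) + 5.0
        _, stats = zscore_columns(train)
        z, _ = zscore_columns(test, stats)
        np.testing.assert_allclose(z, (test - stats["mean"]) / stats["sd"])
        assert np.all(np.abs(z.mean(0)) > 1.0)     # test means not re-centred


class TestRidgeGCV:
    def test_lambda_grid_spec(self):
        grid = default_lambda_grid()
        assert len(grid) == 25
        np.testing.assert_allclose(grid[0], 1e-6)
        np.testing.assert_allclose(grid[-1], 1e6)
        np.testing.assert_allclose(np.diff(np.log10(grid)), 0.5)

    @pytest.mark.parametrize("lam", [1e-4, 1.0, 3.7, 1e3])
    def test_matches_primal_and_dual_solutions(self, lam, rng):
        S = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 3))
        coef, _, _, _ = ridge_gcv(S, Y, np.array([lam]))
        primal = np.linalg.solve(S.T @ S + lam * np.eye(5), S.T @ Y)
        dual = S.T @ np.linalg.solve(S @ S.T + lam * np.eye(30), Y)
        np.testing.assert_allclose(coef, primal, atol=1e-8)
        np.testing.assert_allclose(coef, dual, atol=1e-8)

    def test_shrinkage_monotone_in_lambda(self, rng):
        S = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 1))
        norms = [
            np.linalg.norm(ridge_gcv(S, Y, np.array([lam]))[0])
            for lam in default_lambda_grid()
        ]
        assert np.all(np.diff(norms) <= 1e-12)

    def test_selected_lambda_attains_gcv_minimum(self, rng):
        S = rng.standard_normal((60, 8))
        Y = S @ rng.standard_normal((8, 4)) + 0.5 * rng.standard_normal((60, 4))
        model = fit_encoding(*[zscore_columns(m)[0] for m in (S, Y)])
        grid = model.lambda_grid
        for v in range(4):
            assert model.lambdas[v] == grid[np.argmin(model.gcv_curves[:, v])]

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ridge_gcv(np.full((10, 2), np.nan), np.zeros((10, 1)))


class TestPredict:
    def test_zero_coefficients_predict_zero(self, rng):
        model = fit_encoding(rng.standard_normal((20, 3)), np.zeros((20, 2)))
        model.coef[:] = 0.0
        assert np.all(predict_responses(model, rng.standard_normal((5, 3))) == 0)

    def test_feature_count_mismatch(self, rng):
        model = fit_encoding(rng.standard_normal((20, 3)), rng.standard_normal((20, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            predict_responses(model, rng.standard_normal((5, 4)))


def _brute_force_scores(pred, meas):
    """Independent oracle: per-stimulus rank by explicit correlation loop."""
    n = pred.shape[0]
    scores = np.empty(n)
    for s in range(n):
        rs = np.array([np.corrcoef(pred[s], meas[t])[0, 1] for t in range(n)])
        rank = 1 + np.sum(rs > rs[s]) + 0.5 * (np.sum(rs == rs[s]) - 1)
        scores[s] = 1.0 - (rank - 1.0) / (n - 1.0)
    return scores


class TestIdentification:
    def test_perfect_prediction_scores_one(self, rng):
        y = rng.standard_normal((10, 6))
        res = identification_scores(y, y)
        np.testing.assert_allclose(res.scores, 1.0)
        assert res.accuracy == 1.0

    def test_matches_brute_force_ranks(self, rng):
        for _ in range(5):
            pred = rng.standard_normal((5, 4))
            meas = rng.standard_normal((5, 4))
            res = identification_scores(pred, meas)
            np.testing.assert_allclose(res.scores, _brute_force_scores(pred, meas), atol=1e-12)

    def test_least_similar_scores_zero(self):
        # prediction anti-correlated with its own measurement, perfectly
        # correlated with the others -> correct stimulus ranked last
        meas = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        pred = np.array([[3.0, 1.0, 2.0], [1.0, 2.0, 3.0]])
        res = identification_scores(pred, meas)
        np.testing.assert_allclose(res.scores, 0.0)

    def test_constant_rows_excluded(self, rng):
        pred = rng.standard_normal((4, 3))
        meas = rng.standard_normal((4, 3))
        pred[1] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            res = identification_scores(pred, meas)
        assert np.isnan(res.scores[1]) and 1 in res.excluded


class TestMarginals:
    def test_uniform_grid_counts(self):
        axes = grid_axes("encoding")
        prof = marginal_mtf(np.ones(axes.n_features), axes)
        np.testing.assert_allclose(prof["rate"].values, 48.0)   # 6 x 8 cells summed
        np.testing.assert_allclose(prof["scale"].values, 48.0)
        np.testing.assert_allclose(prof["frequency"].values, 36.0)

    def test_one_hot_coefficient(self):
        axes = grid_axes("encoding")
        grid = np.zeros(axes.shape)
        grid[2, 2, 3] = 1.0                                     # rate 4 Hz
        prof = marginal_mtf(axes.flatten(grid), axes)
        np.testing.assert_array_equal(prof["rate"].values, [0, 0, 1, 0, 0, 0])

    def test_marginal_sums_conserved(self, rng):
        axes = grid_axes("roi_decoding")
        c = rng.standard_normal(axes.n_features)
        prof = marginal_mtf(c, axes)
        for d in ("rate", "scale", "frequency"):
            np.testing.assert_allclose(prof[d].values.sum(), c.sum())


class TestBestFeatureMaps:
    def test_ties_resolve_to_lowest_axis_value(self):
        axes = grid_axes("roi_decoding")
        bmap = best_feature_map(np.ones((axes.n_features, 2)), axes)
        assert np.all(bmap.rate == axes.rates[0])
        assert np.all(bmap.frequency == axes.freqs[0])

    def test_identical_maps_correlate_perfectly(self, rng):
        vals = np.random.default_rng(0).choice(grid_axes("encoding").freqs, 30)
        assert map_correlation(vals, vals) == pytest.approx(1.0)

    def test_group_map_is_voxelwise_median(self):
        axes = grid_axes("roi_decoding")
        maps = []
        for r in (1.0, 2.4, 32.0):
            m = best_feature_map(np.ones((axes.n_features, 1)), axes)
            m.rate = np.array([r])
            maps.append(m)
        assert group_map(maps).rate[0] == 2.4

    def test_noiseless_recovery_matches_ground_truth(
        self, roi_features_convolved, roi_features_standardized
    ):
        co = synthetic.make_cohort(1, 1, 130, bandwidth_young=1e-6,
                                   bandwidth_old=1e-6, noise_sd=0.0, seed=4)
        subj = co.subjects[0]
        y = synthetic.simulate_voxels(roi_features_standardized, subj, seed=0)
        res = run_encoding_cv(roi_features_convolved, y)
        bmap = best_feature_map(res.model.coef, roi_features_convolved.axes)
        axes = roi_features_convolved.axes
        np.testing.assert_array_equal(bmap.rate, axes.rates[subj.pref_idx[:, 0]])
        np.testing.assert_array_equal(bmap.scale, axes.scales[subj.pref_idx[:, 1]])
        np.testing.assert_array_equal(bmap.frequency, axes.freqs[subj.pref_idx[:, 2]])
        assert res.mean_accuracy > 0.999


class TestCrossValidation:
    def test_eight_runs_four_folds_two_held_out(self):
        labels = np.repeat(np.arange(8), 519)
        folds = cv_folds(labels, 4)
        assert len(folds) == 4
        for train, test in folds:
            assert len(train) == 3114 and len(test) == 1038
        # held-out run pairs are consecutive and disjoint
        held = [np.unique(labels[test]).tolist() for _, test in folds]
        assert held == [[0, 1], [2, 3], [4, 5], [6, 7]]

    def test_four_runs_one_held_out_is_valid(self):
        labels = np.repeat(np.arange(4), 10)
        folds = cv_folds(labels, 4)
        assert all(len(test) == 10 for _, test in folds)

    def test_indivisible_runs_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            cv_folds(np.repeat(np.arange(6), 5), 4)

    def test_noiseless_predictions_track_held_out_responses(
        self, roi_features_convolved, roi_features_standardized
    ):
        co = synthetic.make_cohort(1, 1, 130, noise_sd=0.0, seed=7)
        y = synthetic.simulate_voxels(roi_features_standardized, co.subjects[0], seed=0)
        res = run_encoding_cv(roi_features_convolved, y)
        model = res.fold_models[0]
        train, test = model.fold
        s_te, _ = zscore_columns(roi_features_convolved.values[test],
                                 zscore_columns(roi_features_convolved.values[train])[1])
        y_te, _ = zscore_columns(y.values[test],
                                 zscore_columns(y.values[train])[1])
        pred = predict_responses(model, s_te)
        rs = [np.corrcoef(pred[:, v], y_te[:, v])[0, 1] for v in range(5)]
        assert min(rs) > 0.99
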