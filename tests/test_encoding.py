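"""TRF fitting against closed-form and simulation oracles."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from speechenc import encoding, synthetic
from speechenc.datatypes import FeatureStream, GroundTruth


def _trivial_partition(n):
    all_true = np.ones(n, dtype=bool)
    none = np.zeros(n, dtype=bool)
    return [(all_true, none, none)]


class TestDesignMatrix:
    def test_column_count_at_full_window(self):
        feats = synthetic.gen_feature_stream(50, {"spectrogram": 208}, seed=0)
        X = encoding.build_design_matrix(feats, 400.0)
        assert X.shape == (50, 208 * 41)

    def test_window_zero_equals_feature_matrix(self, small_features):
        X = encoding.build_design_matrix(small_features, 0.0)
        np.testing.assert_array_equal(X, small_features.values.T)

    def test_impulse_shift_semantics(self):
        x = np.zeros((2, 30))
        x[1, 10] = 1.0
        feats = FeatureStream(x, 100.0, ["a", "b"], ["f0", "f1"])
        X = encoding.build_design_matrix(feats, 100.0)  # 11 lags
        # feature 1, lag tau=50 ms (l=5) lives in column 1*11 + 5
        col = X[:, 11 + 5]
        assert col[15] == 1.0 and col.sum() == 1.0

    def test_window_beyond_max_rejected(self, small_features):
        with pytest.raises(ValueError):
            encoding.build_design_matrix(small_features, 500.0)


class TestRidgeOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_fixed_lambda_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 40, 7
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        lam = 10 ** rng.uniform(-2, 2)
        m = encoding.fit_trf(X, y, _trivial_partition(n), [lam],
                             standardize=False, fit_intercept=False)
        oracle = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
        np.testing.assert_allclose(m.weights.ravel(), oracle, atol=1e-8)

    def test_matches_sklearn_ridge(self):
        rng = np.random.default_rng(99)
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        lam = 3.0
        m = encoding.fit_trf(X, y, _trivial_partition(60), [lam],
                             standardize=False, fit_intercept=False)
        sk = Ridge(alpha=lam, fit_intercept=False, solver="cholesky").fit(X, y)
        np.testing.assert_allclose(m.weights.ravel(), sk.coef_, atol=1e-8)

    def test_rank_deficient_zero_lambda_rejected(self):
        X = np.ones((20, 3))  # rank 1
        y = np.arange(20.0)
        with pytest.raises(np.linalg.LinAlgError):
            encoding.fit_trf(X, y, _trivial_partition(20), [0.0],
                             standardize=False, fit_intercept=False)


class TestParameterRecovery:
    def test_noiseless_recovery(self):
        feats = synthetic.gen_feature_stream(3000, {"spectrogram": 10}, seed=1)
        truth = synthetic.gen_ground_truth(1, 10, 6, noise_sd=0.0, seed=2)
        resp = synthetic.gen_neural_responses(feats, truth)
        m = encoding.fit_encoding(feats, resp.activity[0], 50.0,
                                  np.geomspace(1e-6, 1e2, 9))
        assert m.mean_r2 > 0.99
        c = np.corrcoef(m.weights.ravel(), truth.trf_weights.ravel())[0, 1]
        assert c > 0.99

    def test_null_response_gives_near_zero_r2(self):
        rng = np.random.default_rng(30001)
        feats = synthetic.gen_feature_stream(20000, {"spectrogram": 8}, seed=3)
        y = rng.standard_normal(feats.n_frames)
        m = encoding.fit_encoding(feats, y, 50.0)
        assert abs(m.mean_r2) < 0.02

    def test_frame_permutation_leaves_closed_form_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        perm = rng.permutation(50)
        a = encoding.fit_trf(X, y, _trivial_partition(50), [1.0],
                             standardize=False, fit_intercept=False)
        b = encoding.fit_trf(X[perm], y[perm], _trivial_partition(50), [1.0],
                             standardize=False, fit_intercept=False)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-10)

    def test_training_error_monotone_in_lambda(self):
        # training R^2 (1 - SSE/SST) never increases along the ridge path
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 10))
        y = X @ rng.standard_normal(10) + rng.standard_normal(80)
        lams = np.geomspace(1e-3, 1e4, 12)
        r2s = []
        for lam in lams:
            m = encoding.fit_trf(X, y, _trivial_partition(80), [lam],
                                 standardize=False, fit_intercept=False)
            r2s.append(encoding.r_squared(y, X @ m.weights.ravel(), kind="sse"))
        assert np.all(np.diff(r2s) <= 1e-8)


class TestBPS:
    def test_arithmetic_identity_and_masking(self):
        assert encoding.brain_prediction_score(0.2, 0.1) == pytest.approx(2.0)
        assert encoding.brain_prediction_score(0.1, 0.1) == 1.0
        assert np.isnan(encoding.brain_prediction_score(0.1, 0.04))

    def test_vectorized_masking(self):
        r2b = np.array([0.2, 0.05, 0.01, 0.5])
        bps = encoding.brain_prediction_score(np.full(4, 0.1), r2b)
        assert np.isnan(bps[1]) and np.isnan(bps[2])
        np.testing.assert_allclose(bps[[0, 3]], [0.5, 0.2])


class TestSelectWindow:
    def test_true_kernel_support_recovered(self):
        feats = synthetic.gen_feature_stream(4000, {"spectrogram": 4}, seed=6)
        truth = synthetic.gen_ground_truth(1, 4, 16, noise_sd=0.3, seed=7)  # 150-ms kernel
        resp = synthetic.gen_neural_responses(feats, truth)
        w, model, scores = encoding.select_window(
            feats, resp.activity[0], window_grid=(0, 50, 100, 150, 200))
        assert w >= 150.0

    def test_grid_of_zero_trivial(self, small_features):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(small_features.n_frames)
        w, model, scores = encoding.select_window(small_features, y, window_grid=(0,))
        assert w == 0.0
        assert abs(model.mean_r2) < 0.05  # white-noise response

    def test_empty_grid_rejected(self, small_features):
        with pytest.raises(ValueError):
            encoding.select_window(small_features, np.zeros(600), window_grid=())


class TestNoiseCeiling:
    def test_identical_repeats_give_one(self, rng):
        trial = rng.standard_normal(100)
        reps = np.stack([np.tile(trial, (5, 1)) for _ in range(3)])
        nc = encoding.noise_ceiling(reps)
        assert nc.r[0] == pytest.approx(1.0)
        assert nc.r2[0] == pytest.approx(1.0)

    def test_two_repeats_reduce_to_pairwise_correlation(self, rng):
        s1, s2 = rng.standard_normal((2, 200))
        nc = encoding.noise_ceiling(np.stack([np.stack([s1, s2])]))
        expected = np.corrcoef(s1, s2)[0, 1]
        assert nc.r[0] == pytest.approx(expected, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        rs = []
        for _ in range(50):
            reps = rng.standard_normal((4, 6, 300))
            rs.append(encoding.noise_ceiling(reps).r[0])
        assert abs(np.mean(rs)) < 0.05

    def test_constant_trial_excluded_with_warning(self, rng):
        s = rng.standard_normal((3, 50))
        s[1] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            nc = encoding.noise_ceiling([s])
        assert np.isfinite(nc.r[0])

    def test_single_repeat_rejected(self, rng):
        with pytest.raises(ValueError):
            encoding.noise_ceiling([rng.standard_normal((1, 50))])


class TestUniqueVariance:
    def test_single_set_dependence(self):
        feats = synthetic.gen_feature_stream(4000, {"a": 5, "b": 5}, seed=9)
        rng = np.random.default_rng(9)
        beta = rng.standard_normal(5)
        y = feats.subset(["a"]).values.T @ beta + 0.5 * rng.standard_normal(4000)
        full, d = encoding.unique_variance(y, feats, window_ms=0.0)
        assert abs(d["b"]) < 0.01
        assert d["a"] > 0.5 * full

    def test_duplicated_set_has_no_unique_contribution(self):
        feats = synthetic.gen_feature_stream(3000, {"a": 4}, seed=10)
        dup = FeatureStream(
            np.vstack([feats.values, feats.values]), 100.0,
            ["a"] * 4 + ["a_copy"] * 4,
            [f"x{i}" for i in range(8)])
        rng = np.random.default_rng(10)
        y = feats.values.T @ rng.standard_normal(4) + 0.3 * rng.standard_normal(3000)
        _, d = encoding.unique_variance(y, dup, window_ms=0.0)
        assert abs(d["a"]) < 0.02 and abs(d["a_copy"]) < 0.02

    def test_single_set_stream_rejected(self, rng):
        feats = synthetic.gen_feature_stream(500, {"a": 3}, seed=11)
        with pytest.raises(ValueError):
            encoding.unique_variance(rng.standard_normal(500), feats)

    def test_delta_bounds_on_orthogonal_design(self):
        feats = synthetic.gen_feature_stream(4000, {"a": 3, "b": 3, "c": 3}, seed=12)
        rng = np.random.default_rng(12)
        y = (feats.subset(["a"]).values.T @ rng.standard_normal(3)
             + feats.subset(["b"]).values.T @ rng.standard_normal(3)
             + rng.standard_normal(4000))
        full, d = encoding.unique_variance(y, feats, window_ms=0.0)
        assert all(v >= -0.02 for v in d.values())
        assert sum(d.values()) <= full + 0.02


class TestCeilingBound:
    def test_heldout_r2_bounded_by_noise_ceiling(self):
        # over many simulated electrodes with matched noise, model R^2 does
        # not exceed the repeat-reliability ceiling by more than 0.05
        reps, truth = synthetic.gen_repeated_trial_block(
            n_sentences=4, n_repeats=6, n_electrodes=20, T=250,
            noise_sd=1.0, n_features=6, n_lags=6, seed=13)
        rng = np.random.default_rng(14)
        feats = synthetic.gen_feature_stream(3000, {"spectrogram": 6}, seed=14)
        X = encoding.build_design_matrix(feats, 50.0)
        clean = X @ truth.trf_weights.reshape(20, -1).T
        excesses = []
        for e in range(20):
            y = clean[:, e] + rng.standard_normal(3000)
            m = encoding.fit_trf(X, y, encoding.cv_partitions(3000),
                                 n_features=6, window_ms=50.0)
            nc = encoding.noise_ceiling(reps[e])
            excesses.append(m.mean_r2 - nc.r2[0])
        assert np.mean(excesses) <= 0.05
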