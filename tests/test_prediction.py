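import numpy as np
import pytest

from eegcomplexity import (
    PredictionModel,
    cpm_score,
    crossval_predict,
    fit_full_model,
    permutation_test_internal,
    predict_external,
    select_features,
    simulate_feature_cohort,
    stratified_folds,
)
from eegcomplexity.prediction import _safe_pearson


def _cohort_arrays(df):
    fc = [c for c in df.columns if c.startswith("feat_")]
    return (
        df[fc].to_numpy(float),
        df["score"].to_numpy(float),
        df[["age", "n_removed_epochs"]].to_numpy(float),
        fc,
    )


class TestSelectFeatures:
    def test_null_selection_rate_matches_alpha(self):
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(30):
            X = rng.standard_normal((150, 161))
            y = rng.standard_normal(150)
            Xz = (X - X.mean(0)) / X.std(0)
            yz = (y - y.mean()) / y.std()
            pos, neg = select_features(Xz, yz, 0.05)
            counts.append(pos.sum() + neg.sum())
        # expected alpha * p = 8.05 selections under the null
        assert np.mean(counts) == pytest.approx(161 * 0.05, abs=2.5)

    def test_exact_feature_lands_in_positive_mask(self):
        y = np.random.default_rng(1).standard_normal(100)
        yz = (y - y.mean()) / y.std()
        X = np.column_stack([yz, -yz, np.random.default_rng(2).standard_normal(100)])
        pos, neg = select_features(X, yz)
        assert pos[0] and not neg[0]
        assert neg[1] and not pos[1]


class TestCpmScore:
    def test_printed_formula_example(self):
        # one subject: positive features z = [1, 3], negative feature z = [-2]
        Xz = np.array([[1.0, 3.0, -2.0]])
        pos = np.array([True, True, False])
        neg = np.array([False, False, True])
        # |mean X+| + |mean X-| = |2| + |-2| = 4
        assert cpm_score(Xz, pos, neg, signed=False)[0] == pytest.approx(4.0)
        # the signed network-strength convention coincides here: 2 - (-2) = 4
        assert cpm_score(Xz, pos, neg, signed=True)[0] == pytest.approx(4.0)

    def test_zero_features_predict_zero(self):
        Xz = np.zeros((3, 5))
        pos = np.array([True, False, False, False, False])
        neg = np.array([False, True, False, False, False])
        np.testing.assert_array_equal(cpm_score(Xz, pos, neg), 0.0)

    def test_beta1_scales_linearly_and_is_inert_for_correlation(self):
        rng = np.random.default_rng(3)
        Xz = rng.standard_normal((50, 4))
        pos = np.array([True, True, False, False])
        neg = np.array([False, False, True, False])
        a = cpm_score(Xz, pos, neg, beta1=1.0)
        b = cpm_score(Xz, pos, neg, beta1=2.0)
        np.testing.assert_allclose(b, 2 * a)
        y = rng.standard_normal(50)
        assert _safe_pearson(a, y) == pytest.approx(_safe_pearson(b, y), abs=1e-12)

    def test_empty_masks_give_constant_zero(self):
        Xz = np.random.default_rng(4).standard_normal((10, 3))
        empty = np.zeros(3, dtype=bool)
        np.testing.assert_array_equal(cpm_score(Xz, empty, empty), 0.0)


class TestStratifiedFolds:
    def test_folds_span_the_score_range(self):
        y = np.random.default_rng(0).standard_normal(150)
        folds = stratified_folds(y, 10, np.random.default_rng(1))
        means = [y[folds == f].mean() for f in range(10)]
        assert np.std(means) < 0.25 * y.std()
        assert np.bincount(folds).min() >= 14

    def test_deterministic_given_seed(self):
        y = np.random.default_rng(2).standard_normal(100)
        a = stratified_folds(y, 10, np.random.default_rng(7))
        b = stratified_folds(y, 10, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestCrossval:
    def test_planted_effect_recovered_within_band(self):
        rs = []
        for seed in range(5):
            df = simulate_feature_cohort(150, {"spectral_exponent": 0.5}, seed=seed)
            X, y, C, _ = _cohort_arrays(df)
            rs.append(crossval_predict(X, y, C, seed=seed)[2])
        assert all(r > 0 for r in rs)
        assert 0.2 <= np.mean(rs) <= 0.6

    def test_permuted_scores_center_on_zero(self):
        df = simulate_feature_cohort(150, {"spectral_exponent": 0.5}, seed=9)
        X, y, C, _ = _cohort_arrays(df)
        rng = np.random.default_rng(0)
        rs = [crossval_predict(X, rng.permutation(y), C, seed=s)[2] for s in range(10)]
        assert abs(np.mean(rs)) < 0.1

    def test_fold_assignment_deterministic(self):
        df = simulate_feature_cohort(80, {}, seed=1)
        X, y, C, _ = _cohort_arrays(df)
        a = crossval_predict(X, y, C, seed=3)
        b = crossval_predict(X, y, C, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]

    def test_no_information_leak_from_test_scores(self):
        """Shuffling scores inside a test fold never changes its predictions."""
        df = simulate_feature_cohort(100, {"alpha_power": 0.4}, seed=4)
        X, y, C, _ = _cohort_arrays(df)
        folds = stratified_folds(y, 10, np.random.default_rng(5))
        yhat_a, _, _ = crossval_predict(X, y, C, folds=folds)
        y2 = y.copy()
        test = folds == 0
        y2[test] = np.random.default_rng(6).permutation(y2[test])
        yhat_b, _, _ = crossval_predict(X, y2, C, folds=folds)
        np.testing.assert_allclose(yhat_a[test], yhat_b[test])


class TestInternalPermutation:
    def test_planted_effect_is_significant(self):
        df = simulate_feature_cohort(150, {"spectral_exponent": 0.5}, seed=0)
        X, y, C, _ = _cohort_arrays(df)
        res = permutation_test_internal(X, y, C, n_divisions=10, n_perm=100, seed=0)
        assert res.p_value < 0.05
        assert res.significant

    def test_null_distribution_contains_exact_zeros(self):
        """With few candidates, some permutations select nothing -> r = 0."""
        df = simulate_feature_cohort(150, {}, n_candidates=20, seed=1)
        fc = [c for c in df.columns if c.startswith("feat_")]
        res = permutation_test_internal(
            df[fc].to_numpy(), df["score"].to_numpy(),
            df[["age", "n_removed_epochs"]].to_numpy(float),
            n_divisions=5, n_perm=100, seed=2,
        )
        assert (res.null_distribution == 0.0).any()

    def test_p_value_in_valid_range(self):
        df = simulate_feature_cohort(100, {}, seed=3)
        X, y, C, _ = _cohort_arrays(df)
        res = permutation_test_internal(X, y, C, n_divisions=5, n_perm=50, seed=4)
        assert 0 < res.p_value <= 1


class TestExternal:
    def test_generalization_to_independent_cohort(self):
        hits = 0
        for seed in range(5):
            train = simulate_feature_cohort(150, {"spectral_exponent": 0.5}, seed=seed)
            test = simulate_feature_cohort(57, {"spectral_exponent": 0.5}, seed=500 + seed)
            fc = [c for c in train.columns if c.startswith("feat_")]
            model = fit_full_model(train, fc, "score", ["age", "n_removed_epochs"])
            _, r, p = predict_external(
                model, test, fc, "score", ["age", "sex", "n_removed_epochs"], seed=seed
            )
            if r > 0 and p < 0.05:
                hits += 1
        assert hits >= 4

    def test_independent_scores_give_null_r(self):
        train = simulate_feature_cohort(150, {"spectral_exponent": 0.5}, seed=7)
        test = simulate_feature_cohort(200, {}, seed=8)
        fc = [c for c in train.columns if c.startswith("feat_")]
        model = fit_full_model(train, fc, "score", ["age", "n_removed_epochs"])
        _, r, _ = predict_external(model, test, fc, "score", ["age"], seed=9)
        assert abs(r) < 0.2

    def test_frozen_model_roundtrip_and_determinism(self, tmp_path):
        train = simulate_feature_cohort(100, {"alpha_power": 0.4}, seed=10)
        test = simulate_feature_cohort(50, {"alpha_power": 0.4}, seed=11)
        fc = [c for c in train.columns if c.startswith("feat_")]
        model = fit_full_model(train, fc, "score", ["age"])
        model.to_json(tmp_path / "model.json")
        loaded = PredictionModel.from_json(tmp_path / "model.json")
        a, ra, _ = predict_external(model, test, fc, "score", ["age"], seed=1)
        b, rb, _ = predict_external(loaded, test, fc, "score", ["age"], seed=1)
        np.testing.assert_allclose(a, b)
        assert ra == rb

    def test_feature_mismatch_rejected(self):
        train = simulate_feature_cohort(100, {}, seed=12)
        fc = [c for c in train.columns if c.startswith("feat_")]
        model = fit_full_model(train, fc, "score", None)
        bad = train.rename(columns={"feat_000": "oops"})
        with pytest.raises(Exception):
            predict_external(model, bad, fc, "score", None)
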