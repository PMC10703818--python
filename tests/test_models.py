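"""Metrics, grid-searched boosting estimators, feature selection and PCA."""

import numpy as np
import pytest

from felgrim.models import (BorutaShapSelector, FGSBinaryClassifier,
                            FGSOrdinalClassifier, FGSRegressor, HyperGrid,
                            RFESelector, StandardizedPCA, auroc,
                            boruta_shap_select, compute_scale_pos_weight, mse,
                            pca_project, rfe_select, shuffled_split)
from felgrim.synthetic import planted_feature_data

TINY_GRID = HyperGrid(n_estimators=(50,), learning_rate=(0.3,),
                      reg_alpha=(0.0,), max_depth=(3,), subsample=(1.0,),
                      colsample_bytree=(1.0,))


def brute_force_auroc(scores, labels):
    """Exhaustive pairwise concordance, ties counted one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestScalePosWeight:
    def test_ratio_of_counts(self):
        assert compute_scale_pos_weight([0] * 80 + [1] * 20) == pytest.approx(4.0)
        assert compute_scale_pos_weight([0, 1] * 10) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_scale_pos_weight([1, 1, 1])
        with pytest.raises(ValueError):
            compute_scale_pos_weight([0, 0])


class TestAUROC:
    def test_perfect_separation_and_all_ties(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_small_example_matches_pair_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
            assert auroc(s, y) == pytest.approx(brute_force_auroc(s, y),
                                                abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestMSE:
    def test_examples_and_loop_oracle(self, rng):
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0
        assert mse([0, 1], [1, 1]) == pytest.approx(0.5)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert mse(a, b) == pytest.approx(
            sum((x - y) ** 2 for x, y in zip(a, b)) / 50)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse([1, 2], [1])


class TestEstimators:
    def test_one_point_grid_five_folds(self):
        X, y = planted_feature_data(80, 3, 2, "binary", seed=0)
        clf = FGSBinaryClassifier(grid=TINY_GRID, random_state=0).fit(X, y)
        assert clf.best_params_ == next(TINY_GRID.combinations())
        assert len(clf.cv_scores_) == 5

    def test_same_seed_reproduces_search(self):
        X, y = planted_feature_data(100, 3, 2, "binary", seed=1)
        grid = HyperGrid(n_estimators=(30, 60), learning_rate=(0.1, 0.3),
                         reg_alpha=(0.0,), max_depth=(2, 3),
                         subsample=(0.8,), colsample_bytree=(1.0,))
        a = FGSBinaryClassifier(grid=grid, random_state=9).fit(X, y)
        b = FGSBinaryClassifier(grid=grid, random_state=9).fit(X, y)
        assert a.best_params_ == b.best_params_
        assert a.cv_scores_ == b.cv_scores_

    def test_separable_data_reaches_perfect_cv_accuracy(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 4))
        y = rng.integers(0, 2, 120)
        X[:, 0] = 2 * y - 1  # perfectly separating two-valued feature
        clf = FGSBinaryClassifier(grid=TINY_GRID, random_state=0).fit(X, y)
        assert np.mean(clf.cv_scores_) == pytest.approx(1.0)

    def test_binary_refit_receives_imbalance_weight(self):
        X, y = planted_feature_data(120, 3, 2, "binary", seed=2)
        y[:90] = 0  # force imbalance
        clf = FGSBinaryClassifier(grid=TINY_GRID, random_state=0).fit(X, y)
        assert clf.scale_pos_weight_() == pytest.approx(
            compute_scale_pos_weight(y))

    def test_regressor_beats_mean_predictor(self):
        X, y = planted_feature_data(300, 4, 2, "regression", seed=4,
                                    label_noise=0.2)
        tr, te = shuffled_split(300, 60, seed=0)
        m = FGSRegressor(grid=TINY_GRID, random_state=0).fit(X[tr], y[tr])
        assert mse(m.predict(X[te]), y[te]) < mse(
            np.full(len(te), y[tr].mean()), y[te])

    def test_ordinal_predictions_in_range(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 3))
        y = np.clip(np.round(X[:, 0] + 1), 0, 2).astype(int)
        m = FGSOrdinalClassifier(grid=TINY_GRID, random_state=0).fit(X, y)
        assert set(np.unique(m.predict(X))) <= {0, 1, 2}

    def test_label_validation(self):
        X = np.zeros((60, 2))
        with pytest.raises(ValueError):
            FGSBinaryClassifier(grid=TINY_GRID).fit(X, np.full(60, 2))
        with pytest.raises(ValueError):
            FGSOrdinalClassifier(grid=TINY_GRID).fit(X, np.full(60, 3))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            HyperGrid(max_depth=(0,))
        with pytest.raises(ValueError):
            HyperGrid(subsample=(1.2,))
        with pytest.raises(ValueError):
            HyperGrid(learning_rate=())


class TestRFE:
    def test_single_feature_returned(self):
        X, y = planted_feature_data(100, 1, 0, "binary", seed=0)
        sel = RFESelector(task="binary").fit(X, y)
        assert sel.selected_ == [0]

    def test_deterministic_under_seed(self):
        X, y = planted_feature_data(200, 4, 4, "binary", seed=6)
        assert rfe_select(X, y, seed=3) == rfe_select(X, y, seed=3)

    def test_planted_recovery_single_seed(self):
        X, y = planted_feature_data(600, 10, 10, "binary", seed=0)
        sel = set(rfe_select(X, y, task="binary", seed=0))
        assert set(range(10)) <= sel
        assert len(sel & set(range(10, 20))) <= 4


class TestBoruta:
    def test_planted_recovery_and_constant_feature(self):
        X, y = planted_feature_data(600, 5, 15, "binary", seed=1)
        X[:, 7] = 1.0  # constant column among the noise block
        sel = BorutaShapSelector(task="binary", n_trials=20,
                                 random_state=1).fit(X, y)
        assert set(range(5)) <= set(sel.selected_)
        assert len(set(sel.selected_) - set(range(5))) <= 2
        assert 7 not in sel.selected_

    def test_null_labels_select_nothing(self):
        X, y = planted_feature_data(400, 5, 10, "binary", seed=2)
        rng = np.random.default_rng(0)
        sel = boruta_shap_select(X, rng.permutation(y), task="binary",
                                 n_trials=10, seed=2)
        assert len(sel) <= 1

    def test_too_few_trials_rejected(self):
        X, y = planted_feature_data(100, 2, 2, "binary", seed=0)
        with pytest.raises(ValueError):
            boruta_shap_select(X, y, n_trials=3)


class TestPCA:
    def test_line_in_3d_explained_by_first_component(self, rng):
        t = rng.normal(size=100)
        X = np.column_stack([t, 2 * t, -t]) + 0.0
        _, ratios = pca_project(X, 3)
        assert ratios[0] == pytest.approx(1.0, abs=1e-6)

    def test_ratios_non_increasing_and_sum_le_one(self, rng):
        X = rng.normal(size=(60, 8))
        _, ratios = pca_project(X, 5)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1 + 1e-9

    def test_full_reconstruction_identity(self, rng):
        X = rng.normal(size=(40, 6))
        p = StandardizedPCA(n_components=6).fit(X)
        Z = (X - X.mean(0)) / X.std(0)
        assert np.abs(p.inverse_standardized(p.transform(X)) - Z).max() < 1e-8

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            coords, _ = pca_project(X, 2)
        assert coords.shape == (30, 2)


class TestSplit:
    def test_shuffled_split_sizes_and_determinism(self):
        tr, te = shuffled_split(120, 20, seed=1)
        assert len(tr) == 100 and len(te) == 20
        assert not set(tr) & set(te)
        tr2, te2 = shuffled_split(120, 20, seed=1)
        assert np.array_equal(tr, tr2) and np.array_equal(te, te2)
        trf, tef = shuffled_split(120, 0.25, seed=1)
        assert len(tef) == 30
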