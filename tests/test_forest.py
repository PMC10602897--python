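"""Weighted forest and iterative-RF contracts and explainability metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guideforest import forest as F
from guideforest import synthetic as S


@pytest.fixture(scope="module")
def planted():
    """y = 3*x0 + 2*x1 + N(0, 0.5) among 50 noise features, n=400."""
    X, y, truth = S.generate_regression(400, n_noise=50, coefs=(3.0, 2.0),
                                        noise_sd=0.5, seed=21)
    return X, y, truth


class TestWeightedForest:
    def test_weight_one_hot_forces_single_split_feature(self, planted):
        X, y, _ = planted
        w = np.zeros(X.shape[1])
        w[0] = 1.0
        f = F.WeightedRandomForest(n_trees=5, seed=3).fit(X, y, feature_weights=w)
        used = {int(v) for t in f.trees_ for v in t.feature if v >= 0}
        assert used == {0}

    def test_importances_sum_to_one(self, planted):
        X, y, _ = planted
        f = F.WeightedRandomForest(n_trees=10, seed=4).fit(X, y)
        assert f.importances_.sum() == pytest.approx(1.0, abs=1e-9)
        assert (f.importances_ >= 0).all()

    def test_reproducible_for_fixed_seed(self, planted):
        X, y, _ = planted
        a = F.WeightedRandomForest(n_trees=8, seed=5).fit(X, y)
        b = F.WeightedRandomForest(n_trees=8, seed=5).fit(X, y)
        np.testing.assert_array_equal(a.importances_, b.importances_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_importance_ranking_agrees_with_sklearn_oracle(self, planted):
        # independent check of the uniform-weight grower against sklearn's RF
        from sklearn.ensemble import RandomForestRegressor

        X, y, _ = planted
        ours = F.WeightedRandomForest(n_trees=40, seed=6).fit(X, y)
        ref = RandomForestRegressor(n_estimators=40, random_state=6).fit(X, y)
        # both must put the two planted features on top
        assert set(np.argsort(ours.importances_)[-2:]) == {0, 1}
        assert set(np.argsort(ref.feature_importances_)[-2:]) == {0, 1}

    def test_stump_forest_prediction_is_piecewise_mean(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 1))
        y = (X[:, 0] > 0).astype(float)
        f = F.WeightedRandomForest(n_trees=20, max_depth=1, seed=8).fit(X, y)
        pred = f.predict(np.array([[-2.0], [2.0]]))
        assert pred[0] < 0.2 and pred[1] > 0.8


class TestIRF:
    def test_iteration1_equals_plain_uniform_forest(self, planted):
        X, y, _ = planted
        cfg = F.IRFConfig(n_iterations=1, n_trees=15, cv_folds=0, seed=9)
        res = F.fit_irf((X, y), cfg)
        train_idx, _ = F.split_train_test(len(y), cfg.train_fraction, cfg.seed)
        direct = F.WeightedRandomForest(
            n_trees=15, min_samples_leaf=cfg.min_samples_leaf,
            max_depth=cfg.max_depth, seed=F.irf_iteration_seed(9, 1),
        ).fit(X[train_idx], y[train_idx])
        np.testing.assert_array_equal(res.importances, direct.importances_)

    def test_final_importances_sum_to_one(self, planted):
        X, y, _ = planted
        res = F.fit_irf((X, y), F.IRFConfig(n_iterations=2, n_trees=10,
                                            cv_folds=0, seed=10))
        assert res.importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_features_rank_top5(self, planted):
        X, y, _ = planted
        res = F.fit_irf((X, y), F.IRFConfig(n_iterations=3, n_trees=25,
                                            cv_folds=0, seed=11))
        top5 = set(np.argsort(res.importances)[-5:])
        assert {0, 1} <= top5

    def test_iteration_amplifies_planted_importance(self):
        # averaged across seeds, planted-mass share grows with iterations
        shares = []
        for seed in range(5):
            X, y, _ = S.generate_regression(300, n_noise=40, coefs=(3.0, 2.0),
                                            noise_sd=0.5, seed=seed)
            res = F.fit_irf((X, y), F.IRFConfig(n_iterations=3, n_trees=15,
                                                cv_folds=0, seed=seed))
            shares.append([imp[:2].sum() for imp in res.iteration_importances])
        shares = np.asarray(shares).mean(axis=0)
        assert shares[-1] > shares[0]

    def test_train_test_disjoint_and_cv_partitions(self, planted):
        X, y, _ = planted
        cfg = F.IRFConfig(n_iterations=1, n_trees=5, cv_folds=3, seed=12)
        res = F.fit_irf((X, y), cfg)
        assert set(res.train_idx).isdisjoint(res.test_idx)
        assert len(res.train_idx) + len(res.test_idx) == len(y)
        assert len(res.cv_metrics) == 3

    def test_reproducibility(self, planted):
        X, y, _ = planted
        cfg = F.IRFConfig(n_iterations=2, n_trees=10, cv_folds=0, seed=13)
        a = F.fit_irf((X, y), cfg)
        b = F.fit_irf((X, y), cfg)
        np.testing.assert_array_equal(a.importances, b.importances)
        assert a.metrics == b.metrics

    def test_small_matrix_rejected(self):
        X = np.zeros((10, 3))
        y = np.arange(10.0)
        with pytest.raises(F.FitError):
            F.fit_irf((X, y), F.IRFConfig(n_iterations=1, n_trees=2, cv_folds=0))

    def test_classification_requires_two_classes(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        y = np.ones(30)
        with pytest.raises(F.FitError):
            F.fit_irf((X, y), F.IRFConfig(n_iterations=1, n_trees=2, cv_folds=0,
                                          mode="classification"))

    def test_classification_mode_recovers_signal(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(300, 10))
        y = (X[:, 0] + 0.3 * rng.normal(size=300) > 0).astype(float)
        res = F.fit_irf((X, y), F.IRFConfig(n_iterations=2, n_trees=25,
                                            cv_folds=0, seed=14,
                                            mode="classification"))
        assert res.metrics["roc_auc"] > 0.85
        assert int(np.argmax(res.importances)) == 0


class TestFeatureEffect:
    def test_perfect_correlation_directions(self):
        rng = np.random.default_rng(15)
        y = rng.normal(size=50)
        X = np.column_stack([y, -y, rng.normal(size=50), np.ones(50)])
        res = F.fit_irf((X, y), F.IRFConfig(n_iterations=1, n_trees=5,
                                            cv_folds=0, seed=15))
        with pytest.warns(UserWarning, match="constant"):
            eff = F.feature_effect((X, y), res)
        assert eff["direction"].tolist()[:2] == [1, -1]
        assert eff["direction"].iloc[3] == 0  # constant column
        np.testing.assert_array_equal(eff["magnitude"], res.importances)

    def test_negative_gc_coefficient_gives_negative_direction(self):
        spec = S.SynthSpec(n_guides=120, seed=16, planted_effects=(("gc", -3.0),),
                           noise_sd=0.1)
        guides, _ = S.generate(spec)
        from guideforest import encode as e

        gc = e.raw_features(guides, features=("gc", "tm"))
        X = gc.to_numpy()
        y = np.array([g.efficiency for g in guides])
        res = F.fit_irf((X, y), F.IRFConfig(n_iterations=1, n_trees=10,
                                            cv_folds=0, seed=16))
        eff = F.feature_effect((X, y), res)
        assert eff["direction"].iloc[0] == -1


class TestSamplesAffected:
    def test_stump_forest_root_feature_reaches_everyone(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 3))
        y = X[:, 0]
        w = np.array([1.0, 0.0, 0.0])
        f = F.WeightedRandomForest(n_trees=5, max_depth=1, seed=17).fit(
            X, y, feature_weights=w
        )
        props = f.feature_row_proportions(X)
        assert props[0] == pytest.approx(1.0)
        assert props[1] == props[2] == 0.0

    def test_unused_feature_is_zero(self, planted):
        X, y, _ = planted
        res = F.fit_irf((X, y), F.IRFConfig(n_iterations=1, n_trees=5,
                                            cv_folds=0, seed=18))
        sa = F.samples_affected((X, y), res)
        used = {int(v) for t in res.forest.trees_ for v in t.feature if v >= 0}
        unused = [j for j in range(X.shape[1]) if j not in used]
        if unused:
            assert (sa["samples_affected"].iloc[unused] == 0).all()
        assert sa["samples_affected"].between(0, 1).all()

    def test_hand_traced_toy_forest(self):
        # 4 rows, one tree: root splits f0 at 0.5, left child splits f1 at 0.5
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        tree = F._Tree(
            feature=np.array([0, 1, -1, -1, -1]),
            threshold=np.array([0.5, 0.5, 0.0, 0.0, 0.0]),
            left=np.array([1, 3, -1, -1, -1]),
            right=np.array([2, 4, -1, -1, -1]),
            n_node=np.array([4, 2, 2, 1, 1]),
            value=np.zeros(5),
        )
        f = F.WeightedRandomForest(n_trees=1)
        f.trees_ = [tree]
        f.n_features_ = 2
        props = f.feature_row_proportions(X)
        # all 4 rows pass the root (f0); only the 2 left rows meet f1
        np.testing.assert_allclose(props, [1.0, 0.5])


class TestEvaluate:
    def test_perfect_predictor(self):
        y = np.arange(10.0)
        m = F.evaluate_predictions(y, y)
        assert m["r2"] == pytest.approx(1.0) and m["pearson"] == pytest.approx(1.0)

    def test_mean_predictor_r2_zero(self):
        y = np.arange(10.0)
        m = F.evaluate_predictions(y, np.full(10, y.mean()))
        assert m["r2"] == pytest.approx(0.0)

    def test_pearson_matches_closed_form(self):
        y_true = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y_pred = np.array([2.0, 1.0, 4.0, 5.0, 3.0])
        m = F.evaluate_predictions(y_true, y_pred)
        a, b = y_true - y_true.mean(), y_pred - y_pred.mean()
        expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert m["pearson"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_rows(self):
        with pytest.raises(F.EvaluationError):
            F.evaluate_predictions([1.0], [1.0])


class TestClassifyTails:
    def test_order_statistics(self):
        labels = F.classify_tails(np.arange(1, 11), n_tail=3)
        assert labels[:3].tolist() == [0, 0, 0]
        assert labels[-3:].tolist() == [1, 1, 1]
        assert np.isnan(labels[3:7]).all()

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="tails"):
            F.classify_tails(np.ones(10), n_tail=2)

    def test_too_large_tail_rejected(self):
        with pytest.raises(ValueError):
            F.classify_tails(np.arange(5), n_tail=3)

    def test_counts_at_scale(self):
        rng = np.random.default_rng(19)
        labels = F.classify_tails(rng.normal(size=10_000), n_tail=2500)
        assert (labels == 0).sum() == 2500
        assert (labels == 1).sum() == 2500
        assert np.isnan(labels).sum() == 5000

    def test_stable_tie_breaking(self):
        labels = F.classify_tails(np.array([1.0, 1.0, 1.0, 2.0]), n_tail=1)
        assert labels[0] == 0  # first of the ties takes the low tail
        assert labels[3] == 1
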