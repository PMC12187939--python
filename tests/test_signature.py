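"""Dependency-signature stage: score combination, OOB attenuation, SHAP
ranking, and the three-branch signature rule."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from regulomics._treeshap import (forest_shap_values, shap_values_bruteforce,
                                  tree_shap_values)
from regulomics.signature import (ForestFit, attenuated_predict,
                                  combine_dependency, dependency_auc,
                                  fit_models, select_signature, shap_ranking,
                                  top_shap_features)
from regulomics.simulate import SyntheticSpec, simulate_dependency_dataset


class TestCombineDependency:
    def test_weighted_average(self):
        out = combine_dependency(pd.Series({"a": -1.0}),
                                 pd.Series({"a": -0.5}))
        assert out.loc["a", "combined"] == pytest.approx(-0.9)

    def test_zero_scores(self):
        out = combine_dependency(pd.Series({"a": 0.0}), pd.Series({"a": 0.0}))
        assert out.loc["a", "combined"] == 0.0

    def test_missing_demeter_falls_back_flagged(self):
        out = combine_dependency(pd.Series({"a": -1.2, "b": -0.4}),
                                 pd.Series({"a": -0.5, "b": np.nan}))
        assert out.loc["b", "combined"] == -0.4
        assert bool(out.loc["b", "demeter_missing"])
        assert not bool(out.loc["a", "demeter_missing"])


def _fake_fit(oob_scores, constants, n_features=3):
    """ForestFit whose trees predict given constants regardless of input."""
    trees = []
    for c in constants:
        t = DecisionTreeRegressor(max_depth=1)
        t.fit([[0.0] * n_features, [1.0] * n_features], [c, c])
        trees.append(t)

    class Forest:
        estimators_ = trees

    from regulomics.signature import _weights_from_oob

    weights, fallback = _weights_from_oob(np.asarray(oob_scores, float))
    return ForestFit(Forest(), np.asarray(oob_scores, float), weights, 0,
                     np.arange(2), np.arange(2), fallback)


class TestAttenuatedPredict:
    def test_zero_oob_tree_has_no_weight(self):
        fit = _fake_fit([0.5, 0.0], [1.0, 3.0])
        assert attenuated_predict(fit, [[0.2, 0.2, 0.2]])[0] == pytest.approx(1.0)

    def test_proportional_weights(self):
        fit = _fake_fit([0.6, 0.2], [1.0, 3.0])
        assert attenuated_predict(fit, [[0.2, 0.2, 0.2]])[0] == pytest.approx(1.5)

    def test_equal_oob_equals_plain_mean(self):
        fit = _fake_fit([0.4, 0.4], [1.0, 3.0])
        assert attenuated_predict(fit, [[0.2, 0.2, 0.2]])[0] == pytest.approx(2.0)

    def test_all_nonpositive_oob_uniform_fallback(self):
        fit = _fake_fit([-0.2, -0.1], [1.0, 3.0])
        assert fit.uniform_fallback
        assert attenuated_predict(fit, [[0.2, 0.2, 0.2]])[0] == pytest.approx(2.0)

    def test_removing_zero_weight_tree_changes_nothing(self):
        full = _fake_fit([0.5, 0.0, 0.3], [1.0, 9.0, 2.0])
        reduced = _fake_fit([0.5, 0.3], [1.0, 2.0])
        x = [[0.7, 0.7, 0.7]]
        assert attenuated_predict(full, x)[0] == pytest.approx(
            attenuated_predict(reduced, x)[0])


class TestTreeShap:
    def test_matches_bruteforce_shapley(self):
        """Path-dependent tree SHAP equals exact Shapley enumeration."""
        rng = np.random.default_rng(0)
        for trial in range(4):
            X = rng.normal(size=(50, 5))
            y = 2 * X[:, 0] + X[:, 1] * X[:, 2] + 0.1 * rng.normal(size=50)
            tree = DecisionTreeRegressor(max_depth=4,
                                         random_state=trial).fit(X, y)
            Xq = rng.normal(size=(5, 5))
            np.testing.assert_allclose(
                tree_shap_values(tree, Xq),
                shap_values_bruteforce(tree, Xq),
                atol=1e-10,
            )

    def test_additivity(self):
        """SHAP values sum to prediction minus the tree's expectation."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 6))
        y = X[:, 0] - X[:, 3] ** 2
        tree = DecisionTreeRegressor(max_depth=5, random_state=0).fit(X, y)
        Xq = rng.normal(size=(10, 6))
        phi = tree_shap_values(tree, Xq)
        base = tree.tree_.value[0, 0, 0]
        np.testing.assert_allclose(phi.sum(axis=1) + base, tree.predict(Xq),
                                   atol=1e-10)

    def test_weighted_forest_is_weighted_sum(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = X[:, 0] + X[:, 1]
        t1 = DecisionTreeRegressor(max_depth=3, random_state=1).fit(X, y)
        t2 = DecisionTreeRegressor(max_depth=2, random_state=2).fit(X, y)
        Xq = rng.normal(size=(7, 4))
        combo = forest_shap_values([t1, t2], Xq, [0.75, 0.25])
        expected = 0.75 * tree_shap_values(t1, Xq) + 0.25 * tree_shap_values(t2, Xq)
        np.testing.assert_allclose(combo, expected, atol=1e-12)


class TestShapRanking:
    def test_constant_feature_has_zero_importance(self):
        spec = SyntheticSpec(n_cell_lines=60, n_features=20, n_informative=2,
                             seed=4)
        X, dep, _ = simulate_dependency_dataset(spec)
        X["feat_const"] = 1.0
        fits, _ = fit_models(X, dep["combined"],
                             hyperparams={"n_estimators": 30,
                                          "max_features_fraction": 0.3},
                             n_folds=2, seed=4)
        ranking = shap_ranking(fits, X)
        const_imp = ranking.set_index("feature").loc["feat_const",
                                                     "importance"]
        assert const_imp == 0.0

    def test_duplicated_model_importance_is_idempotent(self):
        spec = SyntheticSpec(n_cell_lines=60, n_features=15, n_informative=2,
                             seed=9)
        X, dep, _ = simulate_dependency_dataset(spec)
        fits, _ = fit_models(X, dep["combined"],
                             hyperparams={"n_estimators": 20,
                                          "max_features_fraction": 0.4},
                             n_folds=2, seed=9)
        single = shap_ranking([fits[0]], X)
        doubled = shap_ranking([fits[0], fits[0]], X)
        pd.testing.assert_frame_equal(single, doubled)

    def test_cumulative_share_monotone_to_one(self):
        spec = SyntheticSpec(n_cell_lines=60, n_features=15, n_informative=3,
                             seed=2)
        X, dep, _ = simulate_dependency_dataset(spec)
        fits, _ = fit_models(X, dep["combined"],
                             hyperparams={"n_estimators": 20,
                                          "max_features_fraction": 0.4},
                             n_folds=2, seed=2)
        cum = shap_ranking(fits, X)["cumulative_share"].to_numpy()
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] == pytest.approx(1.0)


class TestSelectSignature:
    @pytest.mark.parametrize(
        "lit, logfc, expected",
        [
            (7, 1.0, True),    # branch 1: literature alone
            (5, 0.20, True),   # branch 2: below the 0.25 knockdown bound
            (5, 0.30, False),
            (2, -0.1, True),   # branch 3: repressed on knockdown
            (2, 0.1, False),
            (1, -5.0, False),  # too few literature sets for any branch
        ],
    )
    def test_three_branch_rule(self, lit, logfc, expected):
        df = pd.DataFrame([{"gene": "G", "in_top_shap": True,
                            "literature_count": lit,
                            "shnrf2_logfc_6h": logfc}])
        assert bool(select_signature(df)["selected"].item()) is expected

    def test_top_shap_required_in_default_scope(self):
        df = pd.DataFrame([{"gene": "G", "in_top_shap": False,
                            "literature_count": 9, "shnrf2_logfc_6h": -1.0}])
        assert not select_signature(df)["selected"].item()
        # alternative scope: branches 2/3 do not require top-SHAP membership
        out = select_signature(df, top_shap_scope="first_branch")
        assert bool(out["selected"].item())

    def test_order_invariance(self):
        rows = [
            {"gene": g, "in_top_shap": t, "literature_count": l,
             "shnrf2_logfc_6h": f}
            for g, t, l, f in [("A", True, 7, 1.0), ("B", True, 2, 0.1),
                               ("C", False, 9, -1.0), ("D", True, 5, 0.1)]
        ]
        fwd = select_signature(pd.DataFrame(rows)).set_index("gene")["selected"]
        rev = select_signature(pd.DataFrame(rows[::-1])).set_index("gene")[
            "selected"]
        pd.testing.assert_series_equal(fwd.sort_index(), rev.sort_index())

    def test_top_shap_prefix_monotone_in_share(self):
        ranking = pd.DataFrame(
            {"feature": list("abcde"),
             "importance": [0.4, 0.3, 0.15, 0.1, 0.05],
             "rank": range(1, 6),
             "cumulative_share": np.cumsum([0.4, 0.3, 0.15, 0.1, 0.05])}
        )
        prev = set()
        for share in (0.1, 0.3, 0.5, 0.8, 1.0):
            cur = top_shap_features(ranking, share)
            assert prev <= cur
            prev = cur


class TestFitAndAuc:
    def test_degenerate_recovery(self):
        """Noise-free single-feature target is learned almost perfectly."""
        spec = SyntheticSpec(n_cell_lines=200, n_features=20, n_informative=1,
                             noise_sd=0.0, seed=6)
        X, dep, _ = simulate_dependency_dataset(spec)
        fits, preds = fit_models(X, dep["combined"],
                                 hyperparams={"n_estimators": 200,
                                              "max_features_fraction": 1.0},
                                 seed=6)
        _, r2, _ = dependency_auc(preds)
        assert r2 > 0.95

    def test_determinism(self):
        spec = SyntheticSpec(n_cell_lines=60, n_features=20, n_informative=2,
                             seed=8)
        X, dep, _ = simulate_dependency_dataset(spec)
        hp = {"n_estimators": 20, "max_features_fraction": 0.3}
        _, p1 = fit_models(X, dep["combined"], hyperparams=hp, n_folds=3,
                           seed=8)
        _, p2 = fit_models(X, dep["combined"], hyperparams=hp, n_folds=3,
                           seed=8)
        pd.testing.assert_frame_equal(p1, p2)

    def test_auc_equals_rank_sum_oracle(self):
        """AUC must equal U/(n1·n2) from brute-force pairwise comparison."""
        rng = np.random.default_rng(5)
        y_true = rng.normal(-0.5, 0.6, size=60)
        y_pred = y_true + rng.normal(0, 0.5, size=60)
        preds = pd.DataFrame({"fold": 0, "line": range(60),
                              "y_true": y_true, "y_pred": y_pred})
        auc, _, _ = dependency_auc(preds)
        pos = -y_pred[y_true < -0.5]
        neg = -y_pred[y_true >= -0.5]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_perfect_predictions_auc_one(self):
        y = np.concatenate([np.full(10, -1.0), np.full(10, 0.0)])
        preds = pd.DataFrame({"fold": 0, "line": range(20),
                              "y_true": y, "y_pred": y})
        auc, _, _ = dependency_auc(preds)
        assert auc == 1.0

    def test_single_class_errors(self):
        preds = pd.DataFrame({"fold": 0, "line": range(5),
                              "y_true": np.zeros(5), "y_pred": np.zeros(5)})
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                dependency_auc(preds)

    def test_too_small_max_features_errors(self):
        spec = SyntheticSpec(n_cell_lines=60, n_features=20, n_informative=2,
                             seed=1)
        X, dep, _ = simulate_dependency_dataset(spec)
        with pytest.raises(ValueError, match="max_features"):
            fit_models(X, dep["combined"],
                       hyperparams={"max_features_fraction": 0.001}, seed=1)
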