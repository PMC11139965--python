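"""Shapley attribution: axioms, oracle chain, global importance.

The independent oracle averages marginal contributions over explicitly
enumerated feature orderings (permutation form of the Shapley value),
sharing no code with the subset-enumeration or tree-path routes.
"""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from emgait.shapley import (
    Attribution,
    attribute_dataset,
    global_importance,
    shapley_exact,
    summary_table,
    tree_shap,
    value_function,
)


class LinearModel:
    """f(x) = w . x, a transparent stand-in with closed-form Shapley values."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.w


class SumModel:
    def predict(self, X):
        return np.asarray(X, dtype=float).sum(axis=1)


def permutation_oracle(model, x, background, n):
    """Mean marginal contribution over all n! feature orderings.

    Coalition values are memoized but each comes from value_function;
    the orderings themselves are enumerated explicitly.
    """
    x = np.asarray(x, dtype=float)
    phi = np.zeros(n)
    cache: dict[frozenset, float] = {}

    def v(coalition):
        key = frozenset(coalition)
        if key not in cache:
            cache[key] = value_function(model, x, set(key), background)
        return cache[key]

    perms = list(permutations(range(n)))
    for perm in perms:
        coalition: set[int] = set()
        prev = v(coalition)
        for i in perm:
            coalition = coalition | {i}
            cur = v(coalition)
            phi[i] += cur - prev
            prev = cur
    return phi / len(perms)


class TestValueFunction:
    def test_full_subset_is_prediction(self, rng):
        model = LinearModel([2.0, 1.0, -1.0])
        x = np.array([1.0, 2.0, 3.0])
        bg = rng.standard_normal((10, 3))
        assert value_function(model, x, {0, 1, 2}, bg) == pytest.approx(model.predict([x])[0])

    def test_empty_subset_is_background_mean(self, rng):
        model = LinearModel([2.0, 1.0, -1.0])
        bg = rng.standard_normal((10, 3))
        expected = float(np.mean(model.predict(bg)))
        assert value_function(model, np.ones(3), set(), bg) == pytest.approx(expected)

    def test_linear_closed_form(self):
        model = LinearModel([2.0, 1.0])
        x = np.array([3.0, 5.0])
        bg = np.zeros((4, 2))
        assert value_function(model, x, {0}, bg) == pytest.approx(2.0 * 3.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            value_function(LinearModel([1.0]), np.ones(1), set(), np.empty((0, 1)))


class TestShapleyExact:
    def test_additive_model(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        attr = shapley_exact(SumModel(), x, np.zeros((1, 4)))
        for i, v in enumerate(x):
            assert attr.phi[f"x{i}"] == pytest.approx(v)

    def test_dummy_axiom(self, rng):
        model = LinearModel([1.0, 0.0, 2.0])
        x = rng.standard_normal(3)
        attr = shapley_exact(model, x, rng.standard_normal((8, 3)))
        assert attr.phi["x1"] == pytest.approx(0.0, abs=1e-12)

    def test_local_accuracy(self, rng):
        model = LinearModel(rng.standard_normal(5))
        attr = shapley_exact(model, rng.standard_normal(5), rng.standard_normal((6, 5)))
        assert attr.local_accuracy_gap < 1e-8

    def test_symmetry_duplicated_features(self, rng):
        class PairSum:
            def predict(self, X):
                X = np.asarray(X, dtype=float)
                return X[:, 0] + X[:, 1]

        x = np.array([1.7, 1.7, 0.3])
        bg = np.zeros((5, 3))
        attr = shapley_exact(PairSum(), x, bg)
        assert attr.phi["x0"] == pytest.approx(attr.phi["x1"], abs=1e-8)

    def test_enumeration_bound(self, rng):
        with pytest.raises(ValueError, match="enumeration bound"):
            shapley_exact(SumModel(), np.zeros(16), np.zeros((1, 16)))

    def test_matches_permutation_oracle_forest(self, rng):
        n = 6
        X = rng.uniform(0, 1, (150, n))
        y = 2 * X[:, 0] - X[:, 3] + 0.3 * X[:, 1] * X[:, 2] + rng.normal(0, 0.05, 150)
        forest = RandomForestRegressor(n_estimators=20, max_depth=4, random_state=0).fit(X, y)
        bg = X[:8]
        for x in X[:3]:
            expected = permutation_oracle(forest, x, bg, n)
            attr = shapley_exact(forest, x, bg)
            got = np.array([attr.phi[f"x{i}"] for i in range(n)])
            assert np.allclose(got, expected, atol=1e-6)


class TestTreeShap:
    def test_depth_one_tree(self, rng):
        X = rng.uniform(0, 1, (100, 3))
        y = (X[:, 1] > 0.5).astype(float)
        tree = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        attr = tree_shap(tree, X[0], X[:20])
        assert attr.phi["x0"] == 0.0 and attr.phi["x2"] == 0.0
        assert attr.local_accuracy_gap < 1e-10

    def test_matches_exact_on_forest(self, rng):
        n = 8
        X = rng.uniform(0, 1, (200, n))
        y = 3 * X[:, 0] + X[:, 1] ** 2 - 2 * X[:, 4] + rng.normal(0, 0.05, 200)
        forest = RandomForestRegressor(n_estimators=30, max_depth=5, random_state=1).fit(X, y)
        bg = X[:10]
        for x in X[50:55]:
            a = shapley_exact(forest, x, bg)
            b = tree_shap(forest, x, bg)
            for k in a.phi:
                assert a.phi[k] == pytest.approx(b.phi[k], abs=1e-6)

    def test_local_accuracy_many_instances(self, rng):
        X = rng.uniform(0, 1, (150, 5))
        y = X.sum(axis=1) + rng.normal(0, 0.1, 150)
        forest = RandomForestRegressor(n_estimators=40, max_depth=6, random_state=2).fit(X, y)
        for x in X[:20]:
            attr = tree_shap(forest, x, X[:15])
            assert attr.local_accuracy_gap < 1e-8

    def test_dummy_feature_exact_zero(self, rng):
        X = rng.uniform(0, 1, (100, 4))
        y = X[:, 0] * 2
        forest = RandomForestRegressor(n_estimators=20, max_depth=3, random_state=3).fit(X, y)
        # the model never splits on x3 (pure function of x0)
        used = {f for est in forest.estimators_ for f in est.tree_.feature if f >= 0}
        attr = tree_shap(forest, X[0], X[:10])
        for i in range(4):
            if i not in used:
                assert attr.phi[f"x{i}"] == 0.0

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError, match="tree"):
            tree_shap(LinearModel([1.0]), np.ones(1), np.ones((2, 1)))


class TestGlobalImportance:
    def _attr(self, phi, iid="0"):
        return Attribution(iid, 0.0, phi, sum(phi.values()))

    def test_single_instance(self):
        gi = global_importance([self._attr({"a": -2.0, "b": 1.0})])
        assert gi.importance == {"a": 2.0, "b": 1.0}
        assert gi.rank == {"a": 1, "b": 2}

    def test_ranks_are_permutation(self, rng):
        attrs = [
            self._attr({f"f{i}": float(v) for i, v in enumerate(rng.standard_normal(6))}, str(k))
            for k in range(10)
        ]
        gi = global_importance(attrs)
        assert sorted(gi.rank.values()) == list(range(1, 7))
        assert all(v >= 0 for v in gi.importance.values())

    def test_top_n(self):
        gi = global_importance([self._attr({"a": 1.0, "b": 3.0, "c": 2.0})])
        assert [f for f, _ in gi.top(2)] == ["b", "c"]


class TestSummaryTable:
    def test_positive_driver_positive_direction(self, rng):
        X = pd.DataFrame({"up": rng.uniform(0, 1, 120), "noise": rng.uniform(0, 1, 120)})
        y = 5 * X["up"].to_numpy()
        forest = RandomForestRegressor(n_estimators=30, max_depth=4, random_state=0)
        forest.fit(X.to_numpy(), y)
        attrs = attribute_dataset(forest, X.iloc[:25], X.to_numpy()[:20])
        table = summary_table(attrs, X.iloc[:25])
        row = table.set_index("feature").loc["up"]
        assert row["direction"] > 0.5
        assert row["rank"] == 1

    def test_constant_feature_flagged(self, rng):
        X = pd.DataFrame({"f": rng.uniform(0, 1, 80), "const": np.ones(80)})
        y = X["f"].to_numpy()
        forest = RandomForestRegressor(n_estimators=10, max_depth=3, random_state=0)
        forest.fit(X.to_numpy(), y)
        attrs = attribute_dataset(forest, X.iloc[:10], X.to_numpy()[:10])
        table = summary_table(attrs, X.iloc[:10]).set_index("feature")
        assert bool(table.loc["const", "degenerate"])
        assert table.loc["const", "direction"] == 0.0
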