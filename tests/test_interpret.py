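"""Permutation importance and exact Shapley values against first principles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from eegrecon import FeatureTable, exact_shapley, permutation_importance, train_classifier
from eegrecon.interpret import ImportanceReport, ShapleyResult, rank_features


def brute_force_shapley(model, z, background):
    """Textbook definition: average marginal contribution over all orderings."""
    n, d = z.shape
    m = background.shape[0]

    def value(sample, members):
        hybrid = background.copy()
        hybrid[:, members] = sample[members]
        return model.predict_proba(hybrid).mean(axis=0)

    n_classes = model.predict_proba(z[:1]).shape[1]
    phi = np.zeros((n, d, n_classes))
    orders = list(permutations(range(d)))
    for i in range(n):
        for order in orders:
            members: list[int] = []
            prev = value(z[i], members)
            for j in order:
                members.append(j)
                cur = value(z[i], members)
                phi[i, j] += cur - prev
                prev = cur
    return phi / len(orders)


def feature_table(x, labels, names):
    df = pd.DataFrame(x, columns=names)
    df.insert(0, "label", labels)
    df.insert(0, "record_id", [f"r{i}" for i in range(len(df))])
    return FeatureTable(df, list(names))


from sklearn.base import BaseEstimator, ClassifierMixin


class StubModel(ClassifierMixin, BaseEstimator):
    """Deterministic 'model' defined by an arbitrary probability function."""

    def __init__(self, fn, classes=("healthy", "ictal")):
        self.fn = fn
        self.classes_ = np.array(classes)

    def fit(self, x, y):  # pragma: no cover - satisfies the estimator contract
        return self

    def predict_proba(self, x):
        return self.fn(np.asarray(x))

    def predict(self, x):
        return self.classes_[np.argmax(self.predict_proba(x), axis=1)]


@pytest.fixture(scope="module")
def fitted_rf():
    """Small RF on 3 informative-ish features, plus its train/test tables."""
    rng = np.random.default_rng(9)
    n = 90
    x = rng.normal(size=(n, 3))
    labels = np.array(["healthy", "interictal", "ictal"])[
        (x[:, 0] > 0).astype(int) + (x[:, 2] > 0.5).astype(int)
    ]
    table = feature_table(x, labels, ["mse", "orsr", "cs"])
    model = train_classifier("random_forest", table, seed=0, n_estimators=30)
    return model, table


class TestExactShapley:
    def test_efficiency_axiom(self, fitted_rf):
        model, table = fitted_rf
        bg = feature_table(table.x[:20], table.y[:20], table.feature_names)
        res = exact_shapley(model, table, bg)
        totals = res.values.sum(axis=1)  # (n, classes)
        np.testing.assert_allclose(totals, res.prediction - res.baseline, atol=1e-6)
        np.testing.assert_allclose(
            res.prediction, model.predict_proba(table.x), atol=1e-10
        )

    def test_matches_permutation_average_oracle(self, fitted_rf):
        model, table = fitted_rf
        sub = feature_table(table.x[:20], table.y[:20], table.feature_names)
        bg = feature_table(table.x[20:40], table.y[20:40], table.feature_names)
        res = exact_shapley(model, sub, bg)
        oracle = brute_force_shapley(model, sub.x, bg.x)
        np.testing.assert_allclose(res.values, oracle, atol=1e-10)

    def test_two_feature_projection_model_hand_enumerated(self):
        # f(x1, x2) = x1: phi1 = x1 - mean(bg x1), phi2 = 0
        model = StubModel(lambda x: np.stack([x[:, 0], 1 - x[:, 0]], axis=1))
        z = np.array([[0.9, 5.0], [0.2, -3.0]])
        bgx = np.array([[0.1, 0.0], [0.5, 1.0], [0.3, 2.0]])
        table = feature_table(z, ["ictal", "healthy"], ["a", "b"])
        bg = feature_table(bgx, ["ictal"] * 3, ["a", "b"])
        res = exact_shapley(model, table, bg)
        np.testing.assert_allclose(res.values[:, 0, 0], z[:, 0] - bgx[:, 0].mean(), atol=1e-12)
        np.testing.assert_allclose(res.values[:, 1, 0], 0, atol=1e-12)

    def test_symmetry_for_duplicate_features(self):
        # model symmetric in its two identical-role features
        model = StubModel(lambda x: np.stack([x[:, 0] + x[:, 1], -x[:, 0] - x[:, 1]], axis=1))
        rng = np.random.default_rng(0)
        z = rng.uniform(size=(5, 2))
        z[:, 1] = z[:, 0]
        bgx = rng.uniform(size=(4, 2))
        bgx[:, 1] = bgx[:, 0]
        table = feature_table(z, ["ictal"] * 5, ["a", "b"])
        bg = feature_table(bgx, ["ictal"] * 4, ["a", "b"])
        res = exact_shapley(model, table, bg)
        np.testing.assert_allclose(res.values[:, 0, :], res.values[:, 1, :], atol=1e-12)

    def test_too_many_features_rejected(self, fitted_rf):
        model, table = fitted_rf
        wide = feature_table(
            np.zeros((4, 11)), ["ictal"] * 4, [f"f{i}" for i in range(11)]
        )
        with pytest.raises(ValueError, match="infeasible"):
            exact_shapley(model, wide, wide)

    def test_empty_background_rejected(self, fitted_rf):
        model, table = fitted_rf
        empty = feature_table(table.x[:0], table.y[:0], table.feature_names)
        with pytest.raises(ValueError, match="background"):
            exact_shapley(model, table, empty)


class TestPermutationImportance:
    def test_ignored_feature_has_exactly_zero_importance(self):
        # model consults only column 0; permuting column 1 changes nothing
        model = StubModel(lambda x: np.stack([x[:, 0], 1 - x[:, 0]], axis=1))
        rng = np.random.default_rng(1)
        x = rng.uniform(size=(40, 2))
        labels = np.where(x[:, 0] > 0.5, "healthy", "ictal")
        table = feature_table(x, labels, ["used", "unused"])
        res = permutation_importance(model, table, n_repeats=10, seed=0)
        assert res.mean[1] == 0.0
        assert res.sd[1] == 0.0
        assert res.mean[0] > 0.4

    def test_planted_informative_feature_ranked_first(self):
        rng = np.random.default_rng(2)
        n = 90
        x = rng.normal(size=(n, 3))
        labels = np.array(["healthy", "interictal", "ictal"])[
            np.digitize(x[:, 1], [-0.4, 0.4])
        ]
        table = feature_table(x, labels, ["a", "b", "c"])
        model = train_classifier("random_forest", table, seed=0, n_estimators=50)
        res = permutation_importance(model, table, n_repeats=30, seed=0)
        assert res.mean[1] >= 0.5
        assert res.mean[1] > res.mean[0] and res.mean[1] > res.mean[2]

    def test_deterministic_given_seed(self, fitted_rf):
        model, table = fitted_rf
        a = permutation_importance(model, table, n_repeats=5, seed=3)
        b = permutation_importance(model, table, n_repeats=5, seed=3)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_single_row_rejected(self, fitted_rf):
        model, table = fitted_rf
        one = feature_table(table.x[:1], table.y[:1], table.feature_names)
        with pytest.raises(ValueError, match="at least 2"):
            permutation_importance(model, one)


class TestRanking:
    def _result(self, mean_abs, names):
        d, c = np.asarray(mean_abs).shape
        return ShapleyResult(
            feature_names=names,
            class_order=[f"c{i}" for i in range(c)],
            values=np.broadcast_to(np.asarray(mean_abs)[None], (1, d, c)).copy(),
            baseline=np.zeros(c),
            prediction=np.zeros((1, c)),
        )

    def test_sorted_by_class_averaged_magnitude(self):
        res = self._result([[0.2], [0.05], [0.3]], ["mse", "orsr", "cs"])
        assert rank_features(res) == ["cs", "mse", "orsr"]

    def test_ties_broken_alphabetically(self):
        res = self._result([[0.1], [0.1], [0.1]], ["mse", "orsr", "cs"])
        assert rank_features(res) == ["cs", "mse", "orsr"]

    def test_single_feature(self):
        res = self._result([[0.7, 0.1]], ["only"])
        assert rank_features(res) == ["only"]
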