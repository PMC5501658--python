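"""LogitBoost additive models and logistic-model-tree induction."""

import math

import numpy as np
import pytest

from apogee import (
    AdditiveLogisticModel,
    LogisticModelTree,
    fit_logitboost,
    posterior,
)
from apogee.exceptions import DegenerateModelError, ValidationError


def logloss(model_F, y):
    return float(np.mean(np.logaddexp(0.0, -2.0 * y * model_F)))


def gd_logistic_oracle(X, y, lr=0.5, iters=20000):
    """Brute-force gradient descent on the logistic cost
    sum log(1 + exp(-y w^T x)) with an intercept column."""
    Xb = np.column_stack([np.ones(len(y)), X])
    w = np.zeros(Xb.shape[1])
    for _ in range(iters):
        margin = y * (Xb @ w)
        grad = -(Xb * (y / (1.0 + np.exp(margin)))[:, None]).mean(axis=0)
        w -= lr * grad
    return w


def xor_dataset(seed=7, per_cluster=10, sd=0.15):
    r = np.random.default_rng(seed)
    X, y = [], []
    for cx in (-1, 1):
        for cy in (-1, 1):
            X.append(r.normal([cx, cy], sd, size=(per_cluster, 2)))
            y += [1 if cx * cy > 0 else -1] * per_cluster
    return np.vstack(X), np.array(y)


class TestLogitBoost:
    def test_separable_1d_toy_set(self):
        X = np.array([[-1.0], [-0.9], [0.9], [1.0]])
        y = np.array([-1, -1, 1, 1])  # pathogenic at negative x
        model = fit_logitboost(X, y, 30)
        F = model.decision_function(X)
        assert np.all(np.sign(F) == y)
        # agrees with an independently optimized logistic boundary sign
        w = gd_logistic_oracle(X, y)
        assert np.all(np.sign(X[:, 0] * w[1] + w[0]) == np.sign(F))

    def test_label_flip_negates_model(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=60) > 0, 1, -1)
        m1 = fit_logitboost(X, y, 20)
        m2 = fit_logitboost(X, -y, 20)
        np.testing.assert_allclose(m1.decision_function(X), -m2.decision_function(X),
                                   atol=1e-9)

    def test_zero_iterations_gives_class_prior(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array([1] * 30 + [-1] * 10)
        model = fit_logitboost(X, y, 0)
        for x in X[:5]:
            p_path, p_neut = posterior(model, x)
            assert p_neut == pytest.approx(0.75)
            assert p_path == pytest.approx(0.25)

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(DegenerateModelError):
            fit_logitboost(X, np.ones(10), 5)

    def test_training_logloss_monotone_nonincreasing(self, rng):
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 1] - X[:, 2] > 0, 1, -1)
        losses = [logloss(fit_logitboost(X, y, m).decision_function(X), y)
                  for m in range(0, 25)]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_selected_variables_subset(self, rng):
        X = rng.normal(size=(100, 5))
        y = np.where(X[:, 2] > 0, 1, -1)
        model = fit_logitboost(X, y, 10)
        assert model.selected_variables() <= set(range(5))
        assert 2 in model.selected_variables()


class TestPosterior:
    def test_symmetric_case(self):
        model = AdditiveLogisticModel(n_features=2, intercept=0.0)
        assert posterior(model, [0.0, 0.0]) == (0.5, 0.5)

    def test_closed_form_softmax(self):
        # F_neutral = +1, F_pathogenic = -1 -> P_neutral = e/(e + 1/e)
        model = AdditiveLogisticModel(n_features=1, intercept=1.0)
        p_path, p_neut = posterior(model, [0.0])
        expected = math.e / (math.e + math.exp(-1))
        assert p_neut == pytest.approx(expected, abs=1e-12)
        assert p_neut == pytest.approx(0.8808, abs=1e-4)

    def test_probabilities_sum_to_one(self, rng):
        model = AdditiveLogisticModel(n_features=3, intercept=0.3,
                                      components=[(0, 0.1, 0.5), (2, -0.2, -1.0)])
        for x in rng.normal(size=(1000, 3)):
            p_path, p_neut = posterior(model, x)
            assert p_path + p_neut == pytest.approx(1.0, abs=1e-12)
            assert 0.0 < p_path < 1.0

    def test_sum_to_zero_constraint(self, rng):
        """F_pathogenic + F_neutral = 0 for arbitrary models and inputs."""
        model = AdditiveLogisticModel(n_features=2, intercept=-0.7,
                                      components=[(1, 0.3, 2.0)])
        for x in rng.normal(size=(50, 2)):
            F_neut = model.decision_function(x.reshape(1, -1))[0]
            p_path, p_neut = posterior(model, x)
            F_path = -F_neut
            assert abs(F_path + F_neut) <= 1e-9
            assert p_neut == pytest.approx(math.exp(F_neut) /
                                           (math.exp(F_neut) + math.exp(F_path)), abs=1e-12)

    def test_dimension_mismatch(self):
        model = AdditiveLogisticModel(n_features=2, intercept=0.0)
        with pytest.raises(ValidationError):
            posterior(model, [1.0, 2.0, 3.0])


class TestTreeInduction:
    def test_pure_node_single_leaf_confident(self, rng):
        # an all-neutral region becomes one leaf whose posterior favours
        # neutral everywhere (exercised through the induction internals:
        # the public fit contract requires both classes at the root)
        X = rng.normal(size=(30, 2))
        model = LogisticModelTree()
        model.classes_ = np.array([-1, 1])
        model.n_features_in_ = 2
        model.feature_names_ = ["a", "b"]
        model.boost_iterations_ = 10
        model._region_counter = 0
        model.root_ = model._build(X, np.ones(30), 0, None)
        assert model.root_.is_leaf
        assert (model.predict_pathogenic_proba(rng.normal(size=(20, 2))) < 0.5).all()

    def test_xor_needs_a_split(self):
        X, y = xor_dataset()
        deep = LogisticModelTree(boost_iterations=30).fit(X, y)
        assert (deep.predict(X) == y).mean() == 1.0
        assert deep.n_leaves_ >= 2
        flat = LogisticModelTree(max_depth=0, boost_iterations=50).fit(X, y)
        assert (flat.predict(X) == y).mean() <= 0.75

    def test_depth0_equals_plain_logitboost(self, rng):
        X = rng.normal(size=(50, 3))
        y = np.where(X[:, 0] > 0.2, 1, -1)
        tree = LogisticModelTree(max_depth=0, boost_iterations=15).fit(X, y)
        plain = fit_logitboost(X, y, 15)
        np.testing.assert_allclose(tree.decision_function(X),
                                   plain.decision_function(X), atol=1e-12)

    def test_depth0_matches_logistic_oracle_boundary(self, rng):
        X = np.vstack([rng.normal([0, 0], 1.0, (150, 2)),
                       rng.normal([1.6, 1.2], 1.0, (150, 2))])
        y = np.array([-1] * 150 + [1] * 150)
        tree = LogisticModelTree(max_depth=0, boost_iterations=300).fit(X, y)
        w = gd_logistic_oracle(X, y)
        grid = rng.uniform(-3, 4, size=(2000, 2))
        oracle_call = np.sign(grid @ w[1:] + w[0])
        tree_call = np.where(tree.predict_pathogenic_proba(grid) > 0.5, -1, 1)
        assert (oracle_call == tree_call).mean() >= 0.98

    def test_string_labels_and_proba_columns(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.where(X[:, 0] > 0, "neutral", "pathogenic")
        est = LogisticModelTree(boost_iterations=10).fit(X, y)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert set(est.predict(X)) <= {"neutral", "pathogenic"}
        j = list(est.classes_).index("pathogenic")
        np.testing.assert_allclose(proba[:, j], est.predict_pathogenic_proba(X))

    def test_same_leaf_same_probability(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        est = LogisticModelTree(boost_iterations=5).fit(X, y)
        x = X[0]
        two = np.vstack([x, x])
        p = est.predict_pathogenic_proba(two)
        assert p[0] == p[1]

    def test_threshold_ties_route_left(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0], [0.0], [1.0]] * 4)
        y = np.array([1, 1, -1, -1, 1, -1] * 4)
        est = LogisticModelTree(min_node_size=2, boost_iterations=5).fit(X, y)
        assert not est.root_.is_leaf
        thr = est.root_.split_threshold
        # a point exactly at the threshold goes to the left child
        leaf_at_thr = est._leaf_for(np.array([thr]))
        left_leaves = []

        def collect(node, acc):
            if node.is_leaf:
                acc.append(node)
            else:
                collect(node.left, acc)
                collect(node.right, acc)

        collect(est.root_.left, left_leaves)
        assert leaf_at_thr in left_leaves

    def test_feature_permutation_invariance(self, rng):
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 1] + 0.5 * X[:, 3] > 0, 1, -1)
        perm = [2, 0, 3, 1]
        est1 = LogisticModelTree(boost_iterations=10).fit(X, y)
        est2 = LogisticModelTree(boost_iterations=10).fit(X[:, perm], y)
        Xnew = rng.normal(size=(30, 4))
        np.testing.assert_allclose(est1.predict_pathogenic_proba(Xnew),
                                   est2.predict_pathogenic_proba(Xnew[:, perm]),
                                   atol=1e-9)

    def test_monotone_probability_on_separable_1d(self):
        X = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = np.where(X[:, 0] > 0, 1, -1)
        est = LogisticModelTree(boost_iterations=20).fit(X, y)
        grid = np.linspace(-2.5, 2.5, 200).reshape(-1, 1)
        p = est.predict_pathogenic_proba(grid)
        assert np.all(np.diff(p) <= 1e-9)

    def test_missing_cells_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValidationError, match="missing"):
            LogisticModelTree().fit(X, [1, -1])

    def test_cv_iteration_selection_runs(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        est = LogisticModelTree(cv_select=True, cv_max_iterations=20,
                                random_state=1).fit(X, y)
        assert 1 <= est.boost_iterations_ <= 20


class TestRulesAndSerialization:
    def test_depth0_single_rule(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        est = LogisticModelTree(max_depth=0, boost_iterations=5).fit(X, y)
        rules = est.decision_rules()
        assert len(rules) == 1
        assert rules[0].startswith("IF (always)")

    def test_one_split_two_complementary_rules(self):
        X = np.vstack([np.full((20, 1), -1.0), np.full((20, 1), 1.0)])
        X = X + np.linspace(0, 0.01, 40).reshape(-1, 1)
        y = np.array([-1] * 20 + [1] * 20)
        est = LogisticModelTree(max_depth=1, boost_iterations=5).fit(X, y)
        rules = est.decision_rules()
        assert len(rules) == 2
        assert "<=" in rules[0] and ">" in rules[1]

    def test_rule_count_equals_leaf_count(self, rng):
        X = rng.normal(size=(200, 3))
        y = np.where(np.sin(3 * X[:, 0]) + X[:, 1] > 0, 1, -1)
        est = LogisticModelTree(boost_iterations=10).fit(X, y)

        def leaves(node):
            return 1 if node.is_leaf else leaves(node.left) + leaves(node.right)

        assert len(est.decision_rules()) == leaves(est.root_) == est.n_leaves_

    def test_json_round_trip_exact(self, rng, tmp_path):
        X = rng.normal(size=(120, 3))
        y = np.where(X[:, 0] * X[:, 1] > 0, 1, -1)
        est = LogisticModelTree(boost_iterations=10).fit(X, y)
        path = tmp_path / "model.json"
        est.to_json(path)
        back = LogisticModelTree.from_json(str(path))
        Xnew = rng.normal(size=(50, 3))
        np.testing.assert_array_equal(est.predict_pathogenic_proba(Xnew),
                                      back.predict_pathogenic_proba(Xnew))
        assert back.n_leaves_ == est.n_leaves_
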