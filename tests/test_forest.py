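"""Regression-tree and forest mechanics against independent oracles."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from harf import dataset_from_arrays
from harf.forest import (
    Internal, Leaf, best_split, fit_forest, forest_from_json, forest_predict,
    forest_to_json, grow_tree, node_cost, predict_all, split_gain, tree_leaf,
    tree_weights,
)

from conftest import make_leaf_forest


# ---------------------------------------------------------------------------
# node cost and gain
# ---------------------------------------------------------------------------

def test_node_cost_examples():
    assert node_cost([0.3, 0.3, 0.3]) == 0.0
    assert node_cost([1.0, 3.0]) == 2.0
    with pytest.raises(ValueError):
        node_cost([])


def test_node_cost_matches_variance_oracle():
    rng = np.random.default_rng(7)
    y = rng.normal(size=20)
    # two-pass sample-variance oracle: D = (n-1) * var
    assert node_cost(y) == pytest.approx((len(y) - 1) * np.var(y, ddof=1), rel=1e-12)


def test_split_gain_examples():
    assert split_gain([1.0, 3.0], [1.0], [3.0]) == pytest.approx(2.0)
    assert split_gain([2.0] * 4, [2.0], [2.0] * 3) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        split_gain([1.0, 2.0], [], [1.0, 2.0])
    with pytest.raises(ValueError):
        split_gain([1.0, 2.0], [1.0], [3.0])   # children do not partition parent


def test_split_gain_nonnegative_on_all_bipartitions():
    rng = np.random.default_rng(3)
    y = rng.normal(size=7)
    n = len(y)
    for mask_bits in range(1, 2 ** n - 1):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        assert split_gain(y, y[mask], y[~mask]) >= -1e-10


def brute_force_split(X, y, features):
    """Independent exhaustive search over (feature, midpoint) pairs."""
    best = None
    for j in sorted(features):
        values = np.unique(X[:, j])
        for thr in (values[:-1] + values[1:]) / 2.0:
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            gain = node_cost(y) - node_cost(left) - node_cost(right)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    return best


@pytest.mark.parametrize("seed", range(8))
def test_best_split_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(8, 3))
    y = rng.normal(size=8)
    spec = best_split(X, y, [0, 1, 2])
    gain, j, thr = brute_force_split(X, y, [0, 1, 2])
    assert spec.feature == j
    assert spec.threshold == pytest.approx(thr)
    assert spec.gain == pytest.approx(gain)


def test_best_split_perfect_separation():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    spec = best_split(X, y, [0])
    assert spec.feature == 0
    assert 2.0 < spec.threshold < 3.0
    assert spec.gain == pytest.approx(node_cost(y))


def test_best_split_constant_features_returns_none():
    X = np.ones((5, 2))
    y = np.arange(5.0)
    assert best_split(X, y, [0, 1]) is None


def test_best_split_tie_breaks_to_smallest_feature_then_threshold():
    # features 1 and 0 are identical; gains tie everywhere
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    y = np.array([0.0, 1.0, 1.0, 0.0])   # symmetric: thresholds 0.5 and 2.5 tie
    spec = best_split(X, y, [1, 0])
    assert spec.feature == 0
    assert spec.threshold == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------

def leaves_of(node):
    if isinstance(node, Leaf):
        return [node]
    return leaves_of(node.left) + leaves_of(node.right)


def test_grow_tree_single_leaf_when_n_size_exceeds_n():
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
    tree = grow_tree(X, y, np.ones(5, dtype=int), m=2, n_size=10, rng=rng, K=1)
    assert isinstance(tree, Leaf)
    assert tree.n_members == 5
    np.testing.assert_allclose(tree.mean_response, [y.mean()])


def test_grow_tree_perfectly_separable_toy():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    tree = grow_tree(X, y, np.array([1, 1, 2, 2]), m=1, n_size=1,
                     rng=np.random.default_rng(0), K=2)
    assert isinstance(tree, Internal)
    for leaf in leaves_of(tree):
        members_y = y[leaf.member_indices]
        assert node_cost(members_y) == pytest.approx(0.0)


def test_grow_tree_deterministic_given_seed():
    rng = np.random.default_rng(11)
    X, y = rng.normal(size=(20, 4)), rng.normal(size=20)
    labels = np.ones(20, dtype=int)

    def grow():
        return grow_tree(X, y, labels, m=2, n_size=4,
                         rng=np.random.default_rng(99), K=1)

    def structure(node):
        if isinstance(node, Leaf):
            return ("leaf", tuple(node.member_indices.tolist()))
        return ("split", node.split.feature, node.split.threshold,
                structure(node.left), structure(node.right))

    assert structure(grow()) == structure(grow())


# ---------------------------------------------------------------------------
# forest fitting
# ---------------------------------------------------------------------------

def test_fit_forest_reproducible_and_param_validation(tiny_dataset):
    f1 = fit_forest(tiny_dataset, T=5, m=2, n_size=2, seed=4)
    f2 = fit_forest(tiny_dataset, T=5, m=2, n_size=2, seed=4)
    assert forest_to_json(f1) == forest_to_json(f2)
    with pytest.raises(ValueError):
        fit_forest(tiny_dataset, T=0, m=2, n_size=2, seed=0)
    with pytest.raises(ValueError):
        fit_forest(tiny_dataset, T=1, m=99, n_size=2, seed=0)


def test_single_tree_full_features_no_bootstrap_is_deterministic_cart(tiny_dataset):
    preds = []
    for seed in (0, 123):
        f = fit_forest(tiny_dataset, T=1, m=tiny_dataset.n_features, n_size=2,
                       seed=seed, bootstrap=False)
        preds.append(predict_all(f, tiny_dataset.features))
    np.testing.assert_array_equal(preds[0], preds[1])


def test_leaf_invariants_over_forest(sim_dataset):
    f = fit_forest(sim_dataset, T=20, m=10, n_size=4, seed=5)
    n = sim_dataset.n_samples
    for tree, boot in zip(f.trees, f.bootstrap_indices):
        leaves = leaves_of(tree)
        # class counts across leaves account for every bootstrap draw
        assert sum(leaf.class_counts.sum() for leaf in leaves) == n
        for leaf in leaves:
            assert leaf.member_indices.size > 0
            assert np.all(np.isin(leaf.member_indices, boot))
            assert leaf.class_counts.sum() >= leaf.member_indices.size


# ---------------------------------------------------------------------------
# prediction weights
# ---------------------------------------------------------------------------

def test_tree_weights_explicit_leaf():
    leaf = Leaf(member_indices=np.array([1, 4]), mean_response=np.array([0.5]),
                class_counts=np.array([2, 0]))
    w = tree_weights(leaf, np.zeros(3), n_train=6)
    np.testing.assert_allclose(w, [0, 0.5, 0, 0, 0.5, 0])


def test_single_leaf_tree_uniform_weights(tiny_dataset):
    f = fit_forest(tiny_dataset, T=1, m=1, n_size=99, seed=0, bootstrap=False)
    w = tree_weights(f.trees[0], tiny_dataset.features[0], f.n_train)
    np.testing.assert_allclose(w, np.full(8, 1 / 8))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_weights_are_probability_vectors(seed):
    rng = np.random.default_rng(seed)
    X, y = rng.normal(size=(12, 3)), rng.normal(size=12)
    ds = dataset_from_arrays(X, y, np.ones(12, dtype=int))
    f = fit_forest(ds, T=3, m=2, n_size=3, seed=seed % 1000)
    x = rng.normal(size=3)
    per_tree = np.array([tree_weights(t, x, f.n_train) for t in f.trees])
    assert (per_tree >= 0).all()
    np.testing.assert_allclose(per_tree.sum(axis=1), 1.0, atol=1e-12)
    avg = per_tree.mean(axis=0)     # forest-averaged weights inherit both
    assert (avg >= 0).all()
    assert avg.sum() == pytest.approx(1.0, abs=1e-12)


def test_forest_prediction_two_mean_example():
    """70 trees averaging 0.25 and 30 averaging 0.50 predict 0.325."""
    specs = [(0.25, [1, 0])] * 70 + [(0.50, [0, 1])] * 30
    f = make_leaf_forest(specs, n_train=4)
    pred = forest_predict(f, np.zeros(1), mode="leaf_means")
    assert pred[0] == pytest.approx(0.325)


def test_single_tree_prediction_is_leaf_mean(tiny_dataset):
    f = fit_forest(tiny_dataset, T=1, m=2, n_size=3, seed=2)
    x = tiny_dataset.features[3]
    np.testing.assert_allclose(forest_predict(f, x, mode="leaf_means"),
                               tree_leaf(f.trees[0], x).mean_response)


def test_weight_form_equals_leaf_mean_form_without_bootstrap(tiny_dataset):
    # without duplicates the leaf mean is the mean over distinct members,
    # so the pooled-weight and mean-of-leaf-means forms coincide
    f = fit_forest(tiny_dataset, T=7, m=2, n_size=3, seed=6, bootstrap=False)
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.normal(size=tiny_dataset.n_features)
        np.testing.assert_allclose(forest_predict(f, x, mode="weights"),
                                   forest_predict(f, x, mode="leaf_means"),
                                   atol=1e-12)


def test_chosen_split_beats_all_candidates_on_small_nodes():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = rng.integers(4, 10)
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        spec = best_split(X, y, [0, 1, 2])
        oracle_gain = brute_force_split(X, y, [0, 1, 2])[0]
        assert spec.gain >= oracle_gain - 1e-10


def test_forest_json_roundtrip(tiny_dataset):
    f = fit_forest(tiny_dataset, T=4, m=2, n_size=2, seed=9)
    clone = forest_from_json(forest_to_json(f))
    x = tiny_dataset.features[5]
    np.testing.assert_array_equal(forest_predict(f, x), forest_predict(clone, x))
    assert forest_to_json(clone) == forest_to_json(f)
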