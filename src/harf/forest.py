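"""From-scratch regression trees and Random Forest with class-aware leaves.

The forest here is a standard CART-style regression ensemble: T un-pruned
trees, each grown on a bootstrap sample of the n training rows; at every node
a fresh subset of m of the M features is drawn and the split minimizing the
residual sum of squares (equivalently, maximizing the cost reduction

    C(gamma, eta_P) = D(eta_P) - D(eta_L) - D(eta_R),
    D(eta)          = sum_{i in eta} (y(i) - mu(eta))^2

over candidate features and thresholds) is taken. Nodes with fewer than
``n_size`` samples are not split further.

Two departures from a generic RF make the ensemble heterogeneity-aware
downstream:

* every leaf records the per-cancer-type composition (``class_counts``) of
  the training samples it holds, and
* every leaf records the distinct original-training-set indices of its
  members, so predictions can be expressed through the nearest-neighbour
  weight view: per tree, w_i(x) = 1{i in leaf(x)} / |leaf(x)|, and the
  forest prediction is ybar(x) = sum_i wbar_i(x) y(i) with wbar the tree
  average of the per-tree weights.

Bootstrap duplicates are counted with multiplicity in leaf means and class
counts (those describe the sample the tree was actually fitted to), while the
weight vectors run over distinct original indices.

Split search accepts an optional per-node response transform; the
multivariate forest reuses the whole growth machinery by whitening the
response block with the parent node's covariance (see
:mod:`harf.multivariate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import Dataset

__all__ = [
    "SplitSpec",
    "Leaf",
    "Internal",
    "ForestParams",
    "Forest",
    "node_cost",
    "split_gain",
    "best_split",
    "grow_tree",
    "fit_forest",
    "tree_weights",
    "tree_leaf",
    "forest_predict",
    "predict_all",
    "forest_to_json",
    "forest_from_json",
]


# ---------------------------------------------------------------------------
# node-level cost primitives
# ---------------------------------------------------------------------------

def node_cost(responses) -> float:
    """Sum of squared differences from the node mean.

    For a multi-column response the per-column costs are summed, which is the
    identity-covariance special case of the multivariate node cost.
    """
    y = np.asarray(responses, dtype=float)
    if y.size == 0:
        raise ValueError("node_cost of an empty node is undefined")
    if y.ndim == 1:
        y = y[:, None]
    return float(((y - y.mean(axis=0)) ** 2).sum())


def split_gain(parent_responses, left_responses, right_responses) -> float:
    """Cost reduction D(parent) - D(left) - D(right) for a bipartition."""
    parent = np.sort(np.asarray(parent_responses, dtype=float), axis=0)
    left = np.asarray(left_responses, dtype=float)
    right = np.asarray(right_responses, dtype=float)
    if left.size == 0 or right.size == 0:
        raise ValueError("split children must be non-empty")
    merged = np.sort(np.concatenate([left, right], axis=0), axis=0)
    if merged.shape != parent.shape or not np.allclose(merged, parent):
        raise ValueError("left and right must partition the parent responses")
    return node_cost(parent_responses) - node_cost(left) - node_cost(right)


@dataclass(frozen=True)
class SplitSpec:
    """A chosen split: samples with x[:, feature] <= threshold go left."""

    feature: int
    threshold: float
    gain: float = 0.0


def best_split(X_node, Y_node, candidate_features) -> SplitSpec | None:
    """Exhaustive scan over candidate features and achievable thresholds.

    Thresholds are midpoints between consecutive distinct sorted values of
    each candidate feature within the node, so both children are guaranteed
    non-empty. Ties in gain are broken toward the smallest feature index,
    then the smallest threshold. Returns None when every candidate feature
    is constant within the node.
    """
    X = np.asarray(X_node, dtype=float)
    Z = np.asarray(Y_node, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = X.shape[0]
    if n < 2:
        return None
    parent_cost = float(((Z - Z.mean(axis=0)) ** 2).sum())

    feats = np.sort(np.asarray(list(candidate_features), dtype=int))
    Xc = X[:, feats]                              # (n, m)
    orders = np.argsort(Xc, axis=0, kind="stable")
    cols = np.arange(feats.size)
    xs = Xc[orders, cols]                         # (n, m) sorted per feature
    zs = Z[orders]                                # (n, m, r)
    csum = np.cumsum(zs, axis=0)
    csq = np.cumsum(zs * zs, axis=0)
    k = np.arange(1, n, dtype=float)[:, None, None]
    left_cost = (csq[:-1] - csum[:-1] ** 2 / k).sum(axis=2)
    right_cost = ((csq[-1] - csq[:-1])
                  - (csum[-1] - csum[:-1]) ** 2 / (n - k)).sum(axis=2)
    gains = parent_cost - left_cost - right_cost          # (n-1, m)
    gains[xs[1:] <= xs[:-1]] = -np.inf                    # only distinct-value boundaries

    # feature-major flattening: ties resolve to the smallest feature index,
    # then (ascending row order) the smallest threshold
    flat = gains.T.ravel()
    pos = int(np.argmax(flat))
    if flat[pos] == -np.inf:
        return None                                       # all candidates constant
    col, row = divmod(pos, n - 1)
    thr = float((xs[row, col] + xs[row + 1, col]) / 2.0)
    return SplitSpec(feature=int(feats[col]), threshold=thr,
                     gain=max(float(flat[pos]), 0.0))


# ---------------------------------------------------------------------------
# tree structures
# ---------------------------------------------------------------------------

@dataclass
class Leaf:
    member_indices: np.ndarray    # distinct original training indices, sorted
    mean_response: np.ndarray     # (r,), bootstrap multiplicity honoured
    class_counts: np.ndarray      # (K,), bootstrap multiplicity honoured

    @property
    def n_members(self) -> int:
        return int(self.class_counts.sum())


@dataclass
class Internal:
    split: SplitSpec
    left: "Internal | Leaf"
    right: "Internal | Leaf"


def _make_leaf(Yb, labels_b, orig_idx, K: int) -> Leaf:
    return Leaf(
        member_indices=np.unique(orig_idx),
        mean_response=Yb.mean(axis=0),
        class_counts=np.bincount(labels_b, minlength=K + 1)[1:].astype(int),
    )


def grow_tree(X_boot, Y_boot, labels_boot, m, n_size, rng, *,
              orig_indices=None, K=None, transform=None) -> Internal | Leaf:
    """Grow one un-pruned regression tree on a (bootstrap) sample.

    Parameters
    ----------
    X_boot, Y_boot, labels_boot
        The bootstrap rows (features (nb, M), responses (nb, r) or (nb,),
        integer labels 1..K).
    m, n_size
        Features drawn per node; minimum node size eligible for splitting
        (a node with fewer than ``n_size`` samples becomes a leaf).
    rng
        numpy Generator; consumed once per node for the feature subset.
    orig_indices
        Original training-set index of each bootstrap row (defaults to
        0..nb-1, i.e. no bootstrap).
    transform
        Optional callable Y_sub -> Z_sub applied to the node's responses
        before the split search (identity by default). Leaf statistics are
        always computed from the raw responses.
    """
    X = np.asarray(X_boot, dtype=float)
    Y = np.asarray(Y_boot, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(labels_boot, dtype=int)
    nb, M = X.shape
    if nb == 0:
        raise ValueError("cannot grow a tree on an empty sample")
    if not 1 <= m <= M:
        raise ValueError(f"m must be in 1..{M}, got {m}")
    if orig_indices is None:
        orig_indices = np.arange(nb)
    orig_indices = np.asarray(orig_indices, dtype=int)
    if K is None:
        K = int(labels.max()) if labels.size else 1

    def build(idx: np.ndarray):
        if idx.size < max(n_size, 2):
            return _make_leaf(Y[idx], labels[idx], orig_indices[idx], K)
        Y_node = Y[idx]
        Z_node = Y_node if transform is None else transform(Y_node)
        feats = np.sort(rng.choice(M, size=m, replace=False))
        spec = best_split(X[idx], Z_node, feats)
        if spec is None:
            return _make_leaf(Y_node, labels[idx], orig_indices[idx], K)
        go_left = X[idx, spec.feature] <= spec.threshold
        left = build(idx[go_left])
        right = build(idx[~go_left])
        return Internal(split=spec, left=left, right=right)

    return build(np.arange(nb))


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestParams:
    T: int = 100
    m: int = 10
    n_size: int = 4
    seed: int = 0
    bootstrap: bool = True


@dataclass
class Forest:
    trees: list
    bootstrap_indices: list           # per tree, (n,) original indices drawn
    params: ForestParams
    n_train: int
    X_train: np.ndarray               # kept for routing/vote estimation
    y_train: np.ndarray               # (n, r), for weight-form prediction
    K: int = 1

    @property
    def n_responses(self) -> int:
        return self.y_train.shape[1]


def fit_forest(dataset: Dataset, T: int = 100, m: int = 10, n_size: int = 4,
               seed: int = 0, bootstrap: bool = True, transform_factory=None) -> Forest:
    """Fit T trees, each on its own bootstrap sample and rng stream.

    Per-tree generators are spawned from one root SeedSequence, so the same
    seed yields the same forest regardless of how trees would be scheduled.
    ``transform_factory`` (used by the multivariate forest) maps a node's raw
    response block to the representation the split search should score.
    """
    n = dataset.n_samples
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 1 <= m <= dataset.n_features:
        raise ValueError(f"m must be in 1..{dataset.n_features}, got {m}")
    root = np.random.SeedSequence(seed)
    trees, boots = [], []
    Y = dataset.responses
    for child in root.spawn(T):
        rng = np.random.default_rng(child)
        if bootstrap:
            boot = rng.integers(0, n, size=n)
        else:
            boot = np.arange(n)
        tree = grow_tree(
            dataset.features[boot], Y[boot], dataset.labels[boot],
            m, n_size, rng,
            orig_indices=boot, K=dataset.n_classes, transform=transform_factory,
        )
        trees.append(tree)
        boots.append(boot)
    return Forest(
        trees=trees, bootstrap_indices=boots,
        params=ForestParams(T=T, m=m, n_size=n_size, seed=seed, bootstrap=bootstrap),
        n_train=n, X_train=dataset.features.copy(), y_train=Y.copy(),
        K=dataset.n_classes,
    )


def tree_leaf(tree, x) -> Leaf:
    """Route a sample down one tree to its leaf."""
    node = tree
    x = np.asarray(x, dtype=float)
    while isinstance(node, Internal):
        node = node.left if x[node.split.feature] <= node.split.threshold else node.right
    return node


def tree_weights(tree, x, n_train: int) -> np.ndarray:
    """Nearest-neighbour weights of one tree: uniform over the leaf members."""
    leaf = tree_leaf(tree, x)
    w = np.zeros(n_train)
    w[leaf.member_indices] = 1.0 / leaf.member_indices.size
    return w


def forest_predict(forest: Forest, x, mode: str = "weights") -> np.ndarray:
    """Forest prediction for one sample.

    mode="weights" (default) is the pooled weight form: average the per-tree
    leaf-uniform weights and take the weighted mean of the training
    responses. mode="leaf_means" averages the per-tree leaf means instead;
    the two coincide whenever leaves have equal effective sizes and differ
    only through the weight averaging otherwise.
    """
    if mode == "weights":
        w = np.zeros(forest.n_train)
        for tree in forest.trees:
            w += tree_weights(tree, x, forest.n_train)
        w /= len(forest.trees)
        return w @ forest.y_train
    if mode == "leaf_means":
        means = [tree_leaf(tree, x).mean_response for tree in forest.trees]
        return np.mean(means, axis=0)
    raise ValueError(f"unknown prediction mode {mode!r}")


def predict_all(forest: Forest, X, mode: str = "weights") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.vstack([forest_predict(forest, x, mode=mode) for x in X])


# ---------------------------------------------------------------------------
# serialization (versioned JSON)
# ---------------------------------------------------------------------------

_SCHEMA = "harf-forest/1"


def _node_to_dict(node):
    if isinstance(node, Leaf):
        return {
            "leaf": True,
            "members": node.member_indices.tolist(),
            "mean": node.mean_response.tolist(),
            "counts": node.class_counts.tolist(),
        }
    return {
        "leaf": False,
        "feature": node.split.feature,
        "threshold": node.split.threshold,
        "gain": node.split.gain,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d):
    if d["leaf"]:
        return Leaf(
            member_indices=np.asarray(d["members"], dtype=int),
            mean_response=np.asarray(d["mean"], dtype=float),
            class_counts=np.asarray(d["counts"], dtype=int),
        )
    return Internal(
        split=SplitSpec(feature=d["feature"], threshold=d["threshold"], gain=d["gain"]),
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def forest_to_json(forest: Forest) -> str:
    doc = {
        "schema": _SCHEMA,
        "params": vars(forest.params).copy() if not isinstance(forest.params, ForestParams)
        else {k: getattr(forest.params, k) for k in ("T", "m", "n_size", "seed", "bootstrap")},
        "n_train": forest.n_train,
        "K": forest.K,
        "X_train": forest.X_train.tolist(),
        "y_train": forest.y_train.tolist(),
        "bootstrap_indices": [b.tolist() for b in forest.bootstrap_indices],
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    return json.dumps(doc)


def forest_from_json(text: str) -> Forest:
    doc = json.loads(text)
    if doc.get("schema") != _SCHEMA:
        raise ValueError(f"unsupported forest schema {doc.get('schema')!r}")
    return Forest(
        trees=[_node_from_dict(t) for t in doc["trees"]],
        bootstrap_indices=[np.asarray(b, dtype=int) for b in doc["bootstrap_indices"]],
        params=ForestParams(**doc["params"]),
        n_train=doc["n_train"],
        X_train=np.asarray(doc["X_train"], dtype=float),
        y_train=np.asarray(doc["y_train"], dtype=float),
        K=doc["K"],
    )
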