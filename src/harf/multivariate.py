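"""Multivariate random forest (MRF) and its heterogeneity-aware variant.

When several drugs' responses are predicted jointly, the node cost becomes a
sum of squared Mahalanobis distances,

    D_m(eta) = sum_{i in eta} (y(i) - mu(eta)) Lambda^{-1} (y(i) - mu(eta))^T,

so correlated drug responses are scored in their own metric rather than
axis-by-axis. Lambda is estimated once for the node being split (the parent)
and reused when scoring both children of every candidate split: per-child
re-estimation on a handful of samples is ill-conditioned and would make gains
incomparable across candidate splits. A per-child mode is available for
comparison.

With the parent covariance fixed, the Mahalanobis cost of any subset equals
the ordinary sum-of-squares cost of the whitened responses z = y L, where
L L^T = (Lambda + ridge I)^{-1}. The multivariate forest therefore reuses the
univariate growth machinery verbatim, passing whitening as the per-node
response transform. For r = 1 whitening is a positive rescaling, so the tree
topology matches the univariate fit at the same seed.

mHARF is HARF on top of an MRF: classification is identical (leaf majorities
know nothing about the response dimension) and the prediction is the mean of
the agreeing trees' leaf mean-vectors.
"""

from __future__ import annotations

import numpy as np

from .data_io import Dataset
from . import forest as rf
from .heterogeneity import HarfModel, harf_predict

__all__ = [
    "node_covariance",
    "mahalanobis_cost",
    "whitening_transform",
    "fit_mrf",
    "mharf_fit",
    "mharf_predict",
]

DEFAULT_RIDGE_SCALE = 1e-6


def node_covariance(Y_node) -> np.ndarray:
    """Maximum-likelihood (divide-by-k) response covariance of a node."""
    Y = np.atleast_2d(np.asarray(Y_node, dtype=float))
    centered = Y - Y.mean(axis=0)
    return centered.T @ centered / Y.shape[0]


def _is_degenerate(Y: np.ndarray) -> bool:
    """Responses constant up to float round-off: the node carries no spread."""
    centered = Y - Y.mean(axis=0)
    scale = float(np.mean(Y * Y)) + 1e-30
    return float(np.mean(centered * centered)) <= 1e-24 * scale


def _ridge_for(cov: np.ndarray, ridge) -> float:
    if ridge is not None:
        return float(ridge)
    r = cov.shape[0]
    tr = float(np.trace(cov))
    return DEFAULT_RIDGE_SCALE * tr / r if tr > 0 else 1e-12


def mahalanobis_cost(Y_node, cov=None, ridge=None) -> float:
    """Sum of squared Mahalanobis distances of the node's responses.

    ``cov`` defaults to the node's own ML covariance estimate; pass an
    explicit matrix to score a child under the parent's metric. A small
    ridge (default 1e-6 * trace/r) keeps the inverse defined when the node
    is smaller than the response dimension. A single-row node costs 0.
    """
    Y = np.atleast_2d(np.asarray(Y_node, dtype=float))
    k = Y.shape[0]
    if k < 2 and cov is None:
        return 0.0
    if cov is None and _is_degenerate(Y):
        return 0.0
    lam = node_covariance(Y) if cov is None else np.asarray(cov, dtype=float)
    lam = lam + _ridge_for(lam, ridge) * np.eye(lam.shape[0])
    centered = Y - Y.mean(axis=0)
    sol = np.linalg.solve(lam, centered.T)       # (r, k)
    return float((centered.T * sol).sum())


def whitening_transform(Y_node, ridge=None) -> np.ndarray:
    """Whiten a node's responses by its own covariance: z = y L, L L^T = inv."""
    Y = np.atleast_2d(np.asarray(Y_node, dtype=float))
    if Y.shape[0] < 2 or _is_degenerate(Y):
        return np.zeros_like(Y)
    lam = node_covariance(Y)
    lam = lam + _ridge_for(lam, ridge) * np.eye(lam.shape[0])
    inv = np.linalg.inv(lam)
    inv = (inv + inv.T) / 2.0        # re-symmetrize before the factorization
    L = np.linalg.cholesky(inv)
    return Y @ L


def fit_mrf(dataset: Dataset, T: int = 100, m: int = 10, n_size: int = 4,
            seed: int = 0, bootstrap: bool = True, cov_mode: str = "parent",
            ridge=None) -> rf.Forest:
    """Multivariate forest: univariate growth with the Mahalanobis node cost.

    cov_mode="parent" (default) whitens each node's responses with the
    parent's covariance before the split search; "child" re-estimates the
    covariance inside each candidate child (slow, small fixtures only).
    """
    if cov_mode == "parent":
        # r=1 whitening is a positive per-node rescaling of the responses; it
        # cannot change which split wins, so skip it and make the univariate
        # reduction exact (identical trees at the same seed).
        transform = None if dataset.n_responses == 1 \
            else (lambda Y_node: whitening_transform(Y_node, ridge=ridge))
        return rf.fit_forest(
            dataset, T=T, m=m, n_size=n_size, seed=seed, bootstrap=bootstrap,
            transform_factory=transform,
        )
    if cov_mode != "child":
        raise ValueError(f"unknown cov_mode {cov_mode!r}")
    return _fit_mrf_child_cov(dataset, T, m, n_size, seed, bootstrap, ridge)


def _best_split_child_cov(X_node, Y_node, candidate_features, ridge):
    """Split search scoring each child with its own covariance estimate."""
    X = np.asarray(X_node, dtype=float)
    Y = np.atleast_2d(np.asarray(Y_node, dtype=float))
    n = X.shape[0]
    parent_cost = mahalanobis_cost(Y, ridge=ridge)
    best = None
    for j in sorted(int(j) for j in candidate_features):
        values = np.unique(X[:, j])
        if values.size < 2:
            continue
        for thr in (values[:-1] + values[1:]) / 2.0:
            go_left = X[:, j] <= thr
            gain = (parent_cost
                    - mahalanobis_cost(Y[go_left], ridge=ridge)
                    - mahalanobis_cost(Y[~go_left], ridge=ridge))
            if best is None or gain > best.gain:
                best = rf.SplitSpec(feature=j, threshold=float(thr), gain=float(gain))
    return best


def _fit_mrf_child_cov(dataset, T, m, n_size, seed, bootstrap, ridge):
    # mirrors fit_forest/grow_tree but swaps the split-search routine
    n = dataset.n_samples
    root = np.random.SeedSequence(seed)
    trees, boots = [], []
    for child in root.spawn(T):
        rng = np.random.default_rng(child)
        boot = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        Xb, Yb, lb = dataset.features[boot], dataset.responses[boot], dataset.labels[boot]
        M = Xb.shape[1]

        def build(idx):
            if idx.size < max(n_size, 2):
                return rf._make_leaf(Yb[idx], lb[idx], boot[idx], dataset.n_classes)
            feats = np.sort(rng.choice(M, size=m, replace=False))
            spec = _best_split_child_cov(Xb[idx], Yb[idx], feats, ridge)
            if spec is None:
                return rf._make_leaf(Yb[idx], lb[idx], boot[idx], dataset.n_classes)
            go_left = Xb[idx, spec.feature] <= spec.threshold
            if not go_left.any() or go_left.all():
                return rf._make_leaf(Yb[idx], lb[idx], boot[idx], dataset.n_classes)
            return rf.Internal(spec, build(idx[go_left]), build(idx[~go_left]))

        trees.append(build(np.arange(n)))
        boots.append(boot)
    return rf.Forest(
        trees=trees, bootstrap_indices=boots,
        params=rf.ForestParams(T=T, m=m, n_size=n_size, seed=seed, bootstrap=bootstrap),
        n_train=n, X_train=dataset.features.copy(), y_train=dataset.responses.copy(),
        K=dataset.n_classes,
    )


def mharf_fit(dataset: Dataset, T: int = 100, m: int = 10, n_size: int = 4,
              seed: int = 0, vote_threshold: float = 0.5, bootstrap: bool = True,
              cov_mode: str = "parent", ridge=None) -> HarfModel:
    """Fit an MRF and attach labels: the multivariate HARF model."""
    f = fit_mrf(dataset, T=T, m=m, n_size=n_size, seed=seed, bootstrap=bootstrap,
                cov_mode=cov_mode, ridge=ridge)
    return HarfModel(
        forest=f, train_labels=dataset.labels.copy(), K=dataset.n_classes,
        label_names=list(dataset.label_names), vote_threshold=vote_threshold,
    )


def mharf_predict(model: HarfModel, x, prediction: str = "leaf_means"):
    """Classify-then-predict with the multivariate forest (same rule as HARF)."""
    return harf_predict(model, x, prediction=prediction)
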