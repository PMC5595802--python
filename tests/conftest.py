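import numpy as np
import pytest

from harf import Forest, ForestParams, Leaf, SimulationConfig, dataset_from_arrays, make_dataset
from harf.heterogeneity import HarfModel


@pytest.fixture
def tiny_dataset():
    """8 samples, 3 features, 2 balanced cancer types, deterministic."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(8, 3))
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    y = np.where(labels == 1, 0.3, 0.7) + rng.normal(0, 0.05, size=8)
    return dataset_from_arrays(X, y, labels, label_names=["A", "B"])


@pytest.fixture(scope="session")
def sim_dataset():
    """One default synthetic cohort (25+25, 100 genes), shared across tests."""
    return make_dataset(SimulationConfig(seed=123))


def make_leaf_forest(leaf_specs, n_train=4, r=1, K=2):
    """Forest of single-leaf trees from (mean, class_counts) pairs.

    Handy for the worked toy examples where only leaf statistics matter.
    All leaves claim the same member set {0..n_train-1} so weight-form and
    leaf-mean-form predictions coincide when means equal the training mean.
    """
    trees = []
    for mean, counts in leaf_specs:
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        trees.append(Leaf(
            member_indices=np.arange(n_train),
            mean_response=mean,
            class_counts=np.asarray(counts, dtype=int),
        ))
    return Forest(
        trees=trees,
        bootstrap_indices=[np.arange(n_train) for _ in trees],
        params=ForestParams(T=len(trees), m=1, n_size=1, seed=0, bootstrap=False),
        n_train=n_train,
        X_train=np.zeros((n_train, 1)),
        y_train=np.zeros((n_train, r)),
        K=K,
    )


def make_leaf_harf(leaf_specs, n_train=4, r=1, K=2, vote_threshold=0.5):
    forest = make_leaf_forest(leaf_specs, n_train=n_train, r=r, K=K)
    labels = 1 + (np.arange(n_train) % K)
    return HarfModel(forest=forest, train_labels=labels, K=K,
                     label_names=[f"C{i}" for i in range(1, K + 1)],
                     vote_threshold=vote_threshold)
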