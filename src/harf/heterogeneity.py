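"""Heterogeneity Aware Random Forest (HARF).

HARF treats the cancer type of a test sample as a latent class and infers it
from the forest itself, with no separate classifier: route the sample down
every tree, take the majority cancer type of each leaf reached ("the tree's
vote"), and classify by the mode of the T votes. The response is then
predicted using only the trees whose vote agrees with the inferred type --
trees whose leaf is dominated by that type are the ones best calibrated for
it, while disagreeing trees would drag the prediction toward other types'
mean response.

With two categories an explicit vote threshold can replace the plain
majority: the sample is assigned category 1 iff the fraction of trees voting
1 exceeds the threshold. The Bayes analysis in :mod:`harf.bayes` shows the
optimal threshold sits at 50% only for equi-probable classes with
symmetric per-tree accuracy, which is why the threshold is exposed.

Tie rules (both deterministic): within a leaf, the lowest category index wins
a tied majority; across trees, the lowest category index wins a tied mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import Dataset
from . import forest as rf

__all__ = [
    "HarfModel",
    "leaf_majority",
    "tree_votes",
    "classify_sample",
    "harf_predict",
    "harf_fit",
    "model_to_json",
    "model_from_json",
]


@dataclass
class HarfModel:
    forest: rf.Forest
    train_labels: np.ndarray          # (n,) int in 1..K
    K: int
    label_names: list[str] = field(default_factory=list)
    vote_threshold: float = 0.5       # binary case only

    def __post_init__(self) -> None:
        if not 0.0 < self.vote_threshold < 1.0:
            raise ValueError("vote_threshold must lie strictly between 0 and 1")
        self.train_labels = np.asarray(self.train_labels, dtype=int)
        if not self.label_names:
            self.label_names = [str(c) for c in range(1, self.K + 1)]

    def category_name(self, c: int) -> str:
        return self.label_names[c - 1]


def leaf_majority(leaf: rf.Leaf) -> int:
    """Majority category of a leaf (1-based); ties go to the lowest index."""
    return int(np.argmax(leaf.class_counts)) + 1


def tree_votes(model: HarfModel, x) -> np.ndarray:
    """Leaf-majority category of each tree for sample x."""
    return np.array([leaf_majority(rf.tree_leaf(t, x)) for t in model.forest.trees])


def classify_sample(model: HarfModel, x, votes=None) -> int:
    """Categorize x by the mode of the per-tree leaf-majority votes.

    For K=2 with a non-default threshold t, category 1 is returned iff the
    fraction of trees voting 1 strictly exceeds t.
    """
    if votes is None:
        votes = tree_votes(model, x)
    if model.K == 2 and model.vote_threshold != 0.5:
        frac1 = float(np.mean(votes == 1))
        return 1 if frac1 > model.vote_threshold else 2
    counts = np.bincount(votes, minlength=model.K + 1)[1:]
    return int(np.argmax(counts)) + 1


def harf_predict(model: HarfModel, x, prediction: str = "leaf_means"):
    """Classify x, then predict from the agreeing trees only.

    Returns ``(category, response_vector)``. The default combines the
    selected trees by the unweighted mean of their leaf means (the arithmetic
    the method's toy walkthrough uses); ``prediction="weights"`` instead
    pools the selected trees' leaf-uniform weights over the training set.
    The selected set is never empty: the modal category received at least
    one vote.
    """
    votes = tree_votes(model, x)
    category = classify_sample(model, x, votes=votes)
    selected = np.flatnonzero(votes == category)
    if selected.size == 0:        # threshold rule can pick an unvoted class
        selected = np.arange(len(model.forest.trees))
    if prediction == "leaf_means":
        means = [rf.tree_leaf(model.forest.trees[t], x).mean_response for t in selected]
        return category, np.mean(means, axis=0)
    if prediction == "weights":
        w = np.zeros(model.forest.n_train)
        for t in selected:
            w += rf.tree_weights(model.forest.trees[t], x, model.forest.n_train)
        w /= selected.size
        return category, w @ model.forest.y_train
    raise ValueError(f"unknown prediction mode {prediction!r}")


def harf_fit(dataset: Dataset, T: int = 100, m: int = 10, n_size: int = 4,
             seed: int = 0, vote_threshold: float = 0.5,
             bootstrap: bool = True) -> HarfModel:
    """Fit the forest on all samples and attach the training labels.

    K=1 is allowed; the model then degenerates to an ordinary random forest
    (every tree votes the single category and all trees are selected).
    """
    f = rf.fit_forest(dataset, T=T, m=m, n_size=n_size, seed=seed, bootstrap=bootstrap)
    return HarfModel(
        forest=f,
        train_labels=dataset.labels.copy(),
        K=dataset.n_classes,
        label_names=list(dataset.label_names),
        vote_threshold=vote_threshold,
    )


def predict_all(model: HarfModel, X, prediction: str = "leaf_means"):
    """Vectorized harf_predict: returns (categories (n,), responses (n, r))."""
    cats, preds = [], []
    for x in np.asarray(X, dtype=float):
        c, p = harf_predict(model, x, prediction=prediction)
        cats.append(c)
        preds.append(p)
    return np.array(cats), np.vstack(preds)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_SCHEMA = "harf-model/1"


def model_to_json(model: HarfModel) -> str:
    return json.dumps({
        "schema": _SCHEMA,
        "forest": json.loads(rf.forest_to_json(model.forest)),
        "train_labels": model.train_labels.tolist(),
        "K": model.K,
        "label_names": model.label_names,
        "vote_threshold": model.vote_threshold,
    })


def model_from_json(text: str) -> HarfModel:
    doc = json.loads(text)
    if doc.get("schema") != _SCHEMA:
        raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
    return HarfModel(
        forest=rf.forest_from_json(json.dumps(doc["forest"])),
        train_labels=np.asarray(doc["train_labels"], dtype=int),
        K=doc["K"],
        label_names=list(doc["label_names"]),
        vote_threshold=doc["vote_threshold"],
    )
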