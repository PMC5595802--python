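"""Cross-validation harness, metrics, and the comparison experiments.

Model specs understood by :func:`kfold_cv`:

``rf``
    Integrated random forest over all samples, labels ignored.
``cancer_specific_rf``
    One forest per cancer type; a test sample is scored by its own type's
    model (type known at test time -- the "individual models" setting).
``harf`` / ``mharf``
    Heterogeneity-aware forest (univariate / Mahalanobis-cost multivariate):
    type inferred from leaf majorities, prediction from agreeing trees.
``mrf``
    Multivariate forest without the heterogeneity step.
``one_hot_rf``
    Plain RF over the features augmented with K cancer-type indicator
    columns (type encoded as a feature, available to every node split).
``two_stage_b`` / ``two_stage_c``
    Explicit two-stage competitors: an external classifier (LDA by default)
    assigns the type; B predicts with trees pre-assigned to that type by
    validation error, C predicts with the trees whose leaf majority agrees
    (the HARF rule applied after an external classification).

Pooled metrics are always computed over the union of held-out predictions,
never by averaging per-fold metrics, so folds of unequal size are weighted
by their sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import Dataset
from . import forest as rf
from . import heterogeneity as hg
from . import multivariate as mv

__all__ = [
    "mse",
    "mae",
    "EvalReport",
    "stratified_folds",
    "kfold_cv",
    "top_trees_experiment",
    "fit_two_stage",
    "one_hot_dataset",
    "threshold_sweep",
    "MODEL_SPECS",
]

MODEL_SPECS = ("rf", "cancer_specific_rf", "harf", "mrf", "mharf",
               "one_hot_rf", "two_stage_b", "two_stage_c")


def mse(actual, predicted) -> float:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((a - p) ** 2))


def mae(actual, predicted) -> float:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(np.abs(a - p)))


@dataclass
class EvalReport:
    per_fold: list = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "pooled": self.pooled,
                "config": self.config, "seed": self.seed}


def stratified_folds(labels, k: int, seed: int, stratify: bool = True) -> np.ndarray:
    """Deterministic fold assignment (fold id per sample, 0..k-1).

    Stratified mode deals each class's shuffled samples round-robin across
    folds, so every fold sees every cancer type; it requires at least k
    samples per class.
    """
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < k:
                raise ValueError(
                    f"category {cls} has {idx.size} samples, fewer than k={k}"
                )
            rng.shuffle(idx)
            assignment[idx] = np.arange(idx.size) % k
    else:
        idx = rng.permutation(n)
        assignment[idx] = np.arange(n) % k
    return assignment


def _default_classifier_hook():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    def hook(X_train, labels_train):
        clf = LinearDiscriminantAnalysis()
        clf.fit(X_train, labels_train)
        return lambda X: clf.predict(np.atleast_2d(X))

    return hook


def one_hot_dataset(dataset: Dataset) -> Dataset:
    """Append K binary cancer-type indicator columns to the features."""
    K = dataset.n_classes
    indicators = np.zeros((dataset.n_samples, K))
    indicators[np.arange(dataset.n_samples), dataset.labels - 1] = 1.0
    return Dataset(
        features=np.hstack([dataset.features, indicators]),
        responses=dataset.responses,
        labels=dataset.labels,
        sample_ids=list(dataset.sample_ids),
        feature_ids=list(dataset.feature_ids)
        + [f"is_{name}" for name in dataset.label_names],
        label_names=list(dataset.label_names),
    )


# ---------------------------------------------------------------------------
# two-stage competitors
# ---------------------------------------------------------------------------

@dataclass
class TwoStageModel:
    variant: str                      # "B" or "C"
    harf_model: hg.HarfModel
    classify: object                  # callable X -> labels
    tree_categories: np.ndarray | None = None   # variant B

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        category = int(self.classify(x[None, :])[0])
        trees = self.harf_model.forest.trees
        if self.variant == "C":
            votes = hg.tree_votes(self.harf_model, x)
            selected = np.flatnonzero(votes == category)
        else:
            selected = np.flatnonzero(self.tree_categories == category)
        if selected.size == 0:
            selected = np.arange(len(trees))
        means = [rf.tree_leaf(trees[t], x).mean_response for t in selected]
        return category, np.mean(means, axis=0)


def _categorize_trees(forest: rf.Forest, X_val, y_val, labels_val) -> np.ndarray:
    """Assign each tree the category on which its validation MAE is lowest."""
    T = len(forest.trees)
    cats = np.zeros(T, dtype=int)
    classes = np.unique(labels_val)
    for t, tree in enumerate(forest.trees):
        best_cls, best_err = int(classes[0]), np.inf
        for cls in classes:
            rows = np.flatnonzero(labels_val == cls)
            preds = np.vstack([rf.tree_leaf(tree, X_val[i]).mean_response for i in rows])
            err = mae(y_val[rows], preds)
            if err < best_err:                  # strict: ties keep lower class
                best_cls, best_err = int(cls), err
        cats[t] = best_cls
    return cats


def fit_two_stage(train: Dataset, variant: str, classifier_hook=None,
                  val_frac: float = 0.25, T: int = 100, m: int = 10,
                  n_size: int = 4, seed: int = 0) -> TwoStageModel:
    """Fit a two-stage model on a training set.

    Variant B carves a validation subset (stratified, ``val_frac``) out of
    the training data, fits the forest on the remainder, and categorizes
    each tree by its per-class validation MAE. Variant C fits the forest on
    all training samples (no validation needed). The classifier hook is
    trained on the full training set in both variants.
    """
    if variant not in ("B", "C"):
        raise ValueError("variant must be 'B' or 'C'")
    hook = classifier_hook or _default_classifier_hook()
    classify = hook(train.features, train.labels)
    if variant == "C":
        model = hg.harf_fit(train, T=T, m=m, n_size=n_size, seed=seed)
        return TwoStageModel(variant="C", harf_model=model, classify=classify)

    rng = np.random.default_rng(seed)
    val_mask = np.zeros(train.n_samples, dtype=bool)
    for cls in np.unique(train.labels):
        idx = np.flatnonzero(train.labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_frac * idx.size)))
        n_val = min(n_val, idx.size - 1)        # keep at least one to train on
        val_mask[idx[:n_val]] = True
    sub = train.subset(np.flatnonzero(~val_mask))
    model = hg.harf_fit(sub, T=T, m=m, n_size=n_size, seed=seed)
    cats = _categorize_trees(
        model.forest,
        train.features[val_mask], train.responses[val_mask], train.labels[val_mask],
    )
    return TwoStageModel(variant="B", harf_model=model, classify=classify,
                         tree_categories=cats)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fit_predict(spec, train, test_X, test_labels, params, seed):
    """Fit one model spec on `train`, predict `test_X`.

    Returns (predictions (n, r), predicted categories or None).
    """
    T, m, n_size = params["T"], params["m"], params["n_size"]
    m_eff = min(m, train.n_features)
    if spec == "rf":
        f = rf.fit_forest(train, T=T, m=m_eff, n_size=n_size, seed=seed)
        return rf.predict_all(f, test_X, mode=params["rf_mode"]), None
    if spec == "one_hot_rf":
        aug = one_hot_dataset(train)
        f = rf.fit_forest(aug, T=T, m=min(m, aug.n_features), n_size=n_size, seed=seed)
        K = train.n_classes
        ind = np.zeros((test_X.shape[0], K))
        ind[np.arange(test_X.shape[0]), np.asarray(test_labels) - 1] = 1.0
        return rf.predict_all(f, np.hstack([test_X, ind]), mode=params["rf_mode"]), None
    if spec == "cancer_specific_rf":
        preds = np.zeros((test_X.shape[0], train.n_responses))
        for cls_idx, name in enumerate(train.label_names, start=1):
            rows = np.flatnonzero(train.labels == cls_idx)
            sub = train.subset(rows)
            f = rf.fit_forest(sub, T=T, m=m_eff, n_size=n_size, seed=seed)
            test_rows = np.flatnonzero(np.asarray(test_labels) == cls_idx)
            for i in test_rows:
                preds[i] = rf.forest_predict(f, test_X[i], mode=params["rf_mode"])
        return preds, None
    if spec == "mrf":
        f = mv.fit_mrf(train, T=T, m=m_eff, n_size=n_size, seed=seed)
        return rf.predict_all(f, test_X, mode=params["rf_mode"]), None
    if spec == "harf":
        model = hg.harf_fit(train, T=T, m=m_eff, n_size=n_size, seed=seed,
                            vote_threshold=params["vote_threshold"])
        cats, preds = hg.predict_all(model, test_X, prediction=params["harf_mode"])
        return preds, cats
    if spec == "mharf":
        model = mv.mharf_fit(train, T=T, m=m_eff, n_size=n_size, seed=seed,
                             vote_threshold=params["vote_threshold"])
        cats, preds = hg.predict_all(model, test_X, prediction=params["harf_mode"])
        return preds, cats
    if spec in ("two_stage_b", "two_stage_c"):
        model = fit_two_stage(train, variant=spec[-1].upper(),
                              classifier_hook=params.get("classifier_hook"),
                              T=T, m=m_eff, n_size=n_size, seed=seed)
        cats, preds = [], []
        for x in test_X:
            c, p = model.predict(x)
            cats.append(c)
            preds.append(p)
        return np.vstack(preds), np.array(cats)
    raise ValueError(f"unknown model spec {spec!r}; choose from {MODEL_SPECS}")


def kfold_cv(dataset: Dataset, model_spec: str = "harf", k: int = 3,
             seed: int = 0, stratify: bool = True, T: int = 100, m: int = 10,
             n_size: int = 4, vote_threshold: float = 0.5,
             harf_mode: str = "leaf_means", rf_mode: str = "weights",
             classifier_hook=None) -> EvalReport:
    """k-fold cross-validation of one model spec; per-fold and pooled metrics.

    Misclassification rates are reported for the specs that infer a
    category (harf, mharf, two-stage); NaN otherwise.
    """
    params = {"T": T, "m": m, "n_size": n_size, "vote_threshold": vote_threshold,
              "harf_mode": harf_mode, "rf_mode": rf_mode,
              "classifier_hook": classifier_hook}
    folds = stratified_folds(dataset.labels, k, seed, stratify=stratify)
    all_actual, all_pred = [], []
    all_true_cat, all_pred_cat = [], []
    per_fold = []
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        train = dataset.subset(train_idx)
        test_X = dataset.features[test_idx]
        # recode test labels into the training subset's (possibly shrunk) coding
        test_labels = np.array([
            train.label_names.index(dataset.label_names[c - 1]) + 1
            for c in dataset.labels[test_idx]
        ])
        preds, cats = _fit_predict(model_spec, train, test_X, test_labels,
                                   params, seed)
        actual = dataset.responses[test_idx]
        entry = {"fold_id": fold, "n_test": int(test_idx.size),
                 "mse": mse(actual, preds), "mae": mae(actual, preds)}
        if cats is not None:
            entry["misclassification_rate"] = float(np.mean(cats != test_labels))
            all_true_cat.append(test_labels)
            all_pred_cat.append(cats)
        else:
            entry["misclassification_rate"] = float("nan")
        per_fold.append(entry)
        all_actual.append(actual)
        all_pred.append(preds)
    actual = np.vstack(all_actual)
    pred = np.vstack(all_pred)
    pooled = {"mse": mse(actual, pred), "mae": mae(actual, pred)}
    if all_true_cat:
        tc = np.concatenate(all_true_cat)
        pc = np.concatenate(all_pred_cat)
        pooled["misclassification_rate"] = float(np.mean(pc != tc))
    else:
        pooled["misclassification_rate"] = float("nan")
    cfg = {"model_spec": model_spec, "k": k, "stratify": stratify, "T": T,
           "m": m, "n_size": n_size, "vote_threshold": vote_threshold,
           "harf_mode": harf_mode, "rf_mode": rf_mode}
    return EvalReport(per_fold=per_fold, pooled=pooled, config=cfg, seed=seed)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def top_trees_experiment(dataset: Dataset, split=(0.6, 0.2, 0.2),
                         top_frac: float = 0.5, seed: int = 0, T: int = 100,
                         m: int = 10, n_size: int = 4) -> dict:
    """Are all trees equally useful per cancer type?

    Train a forest on the train split; on the validation split rank trees by
    MAE restricted to each type's samples; evaluate on the test split the
    MAE of (a) all trees vs (b) each sample's own type's top ``top_frac``
    trees. Splits are stratified by type. Returns a dict with both MAEs.
    """
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    part = np.empty(dataset.n_samples, dtype=int)   # 0 train, 1 val, 2 test
    for cls in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cls)
        rng.shuffle(idx)
        n_tr = max(1, int(round(split[0] * idx.size)))
        n_val = max(1, int(round(split[1] * idx.size)))
        if n_tr + n_val >= idx.size:
            raise ValueError("split leaves no test samples for some category")
        part[idx[:n_tr]] = 0
        part[idx[n_tr:n_tr + n_val]] = 1
        part[idx[n_tr + n_val:]] = 2

    train = dataset.subset(np.flatnonzero(part == 0))
    f = rf.fit_forest(train, T=T, m=min(m, train.n_features), n_size=n_size, seed=seed)

    val_idx = np.flatnonzero(part == 1)
    n_keep = max(1, int(np.ceil(top_frac * T)))
    top_per_class = {}
    for cls in np.unique(dataset.labels):
        rows = val_idx[dataset.labels[val_idx] == cls]
        errs = np.empty(T)
        for t, tree in enumerate(f.trees):
            preds = np.vstack([rf.tree_leaf(tree, dataset.features[i]).mean_response
                               for i in rows])
            errs[t] = mae(dataset.responses[rows], preds)
        order = np.argsort(errs, kind="stable")     # ties -> lower tree index
        top_per_class[int(cls)] = order[:n_keep]

    test_idx = np.flatnonzero(part == 2)
    all_preds, top_preds = [], []
    for i in test_idx:
        x = dataset.features[i]
        leaf_means = np.vstack([rf.tree_leaf(tree, x).mean_response for tree in f.trees])
        all_preds.append(leaf_means.mean(axis=0))
        top_preds.append(leaf_means[top_per_class[int(dataset.labels[i])]].mean(axis=0))
    actual = dataset.responses[test_idx]
    return {
        "mae_all_trees": mae(actual, np.vstack(all_preds)),
        "mae_top_trees": mae(actual, np.vstack(top_preds)),
        "top_frac": top_frac,
        "n_test": int(test_idx.size),
        "seed": seed,
    }


def threshold_sweep(dataset: Dataset, thresholds, k: int = 3, seed: int = 0,
                    T: int = 100, m: int = 10, n_size: int = 4) -> list:
    """Pooled HARF metrics per vote threshold, folds and forests shared.

    The threshold only affects the classification rule, so one HARF model is
    fitted per fold and re-used across the whole grid.
    """
    if dataset.n_classes != 2:
        raise ValueError("the vote threshold is a two-category notion")
    folds = stratified_folds(dataset.labels, k, seed, stratify=True)
    fold_models = []
    for fold in range(k):
        train = dataset.subset(np.flatnonzero(folds != fold))
        model = hg.harf_fit(train, T=T, m=min(m, train.n_features),
                            n_size=n_size, seed=seed)
        fold_models.append(model)

    results = []
    for thr in thresholds:
        all_actual, all_pred, miss, total = [], [], 0, 0
        per_fold = []
        for fold in range(k):
            model = fold_models[fold]
            model.vote_threshold = float(thr)
            test_idx = np.flatnonzero(folds == fold)
            cats, preds = hg.predict_all(model, dataset.features[test_idx])
            actual = dataset.responses[test_idx]
            wrong = int(np.sum(cats != dataset.labels[test_idx]))
            per_fold.append({"fold_id": fold, "mse": mse(actual, preds),
                             "mae": mae(actual, preds),
                             "misclassification_rate": wrong / test_idx.size})
            miss += wrong
            total += test_idx.size
            all_actual.append(actual)
            all_pred.append(preds)
        pooled = {"mse": mse(np.vstack(all_actual), np.vstack(all_pred)),
                  "mae": mae(np.vstack(all_actual), np.vstack(all_pred)),
                  "misclassification_rate": miss / total}
        results.append((float(thr), EvalReport(
            per_fold=per_fold, pooled=pooled,
            config={"model_spec": "harf", "vote_threshold": float(thr), "k": k},
            seed=seed,
        )))
    return results
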