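"""CV harness, metrics, and the comparison-experiment plumbing."""

import numpy as np
import pytest

from harf import SimulationConfig, dataset_from_arrays, make_dataset
from harf.forest import fit_forest, predict_all
from harf.evaluate import (
    fit_two_stage, kfold_cv, mae, mse, one_hot_dataset, stratified_folds,
    threshold_sweep, top_trees_experiment,
)


def test_metric_examples_and_oracle():
    assert mse([1, 2], [1, 2]) == 0.0
    assert mae([1, 2], [1, 2]) == 0.0
    assert mse([0, 1], [1, 0]) == 1.0
    assert mae([0, 1], [1, 0]) == 1.0
    rng = np.random.default_rng(0)
    a, p = rng.normal(size=30), rng.normal(size=30)
    assert mse(a, p) == pytest.approx(float(np.mean((a - p) ** 2)))
    assert mae(a, p) == pytest.approx(float(np.mean(np.abs(a - p))))
    with pytest.raises(ValueError):
        mse([1], [1, 2])
    with pytest.raises(ValueError):
        mae([], [])


def test_stratified_folds_cover_every_class():
    labels = np.array([1] * 9 + [2] * 6)
    folds = stratified_folds(labels, k=3, seed=0)
    for fold in range(3):
        fold_labels = labels[folds == fold]
        assert set(fold_labels.tolist()) == {1, 2}
    np.testing.assert_array_equal(folds, stratified_folds(labels, k=3, seed=0))
    with pytest.raises(ValueError):
        stratified_folds(np.array([1, 1, 1, 2, 2]), k=3, seed=0)


def test_pooled_metrics_match_direct_recomputation(sim_dataset):
    """Dual-route check: rebuild the held-out predictions with the same fold
    assignment and forests, and recompute pooled MSE/MAE from the union."""
    report = kfold_cv(sim_dataset, "rf", k=3, seed=4, T=10)
    folds = stratified_folds(sim_dataset.labels, k=3, seed=4)
    actual, preds = [], []
    for fold in range(3):
        train = sim_dataset.subset(np.flatnonzero(folds != fold))
        f = fit_forest(train, T=10, m=10, n_size=4, seed=4)
        test_idx = np.flatnonzero(folds == fold)
        preds.append(predict_all(f, sim_dataset.features[test_idx]))
        actual.append(sim_dataset.responses[test_idx])
    actual, preds = np.vstack(actual), np.vstack(preds)
    assert report.pooled["mse"] == pytest.approx(mse(actual, preds), abs=1e-12)
    assert report.pooled["mae"] == pytest.approx(mae(actual, preds), abs=1e-12)
    # pooled is union-based, not the mean of per-fold metrics
    weights = np.array([e["n_test"] for e in report.per_fold])
    weighted = np.average([e["mse"] for e in report.per_fold], weights=weights)
    assert report.pooled["mse"] == pytest.approx(weighted, abs=1e-12)


def test_misclassification_rate_matches_confusion_oracle(sim_dataset):
    report = kfold_cv(sim_dataset, "harf", k=3, seed=1, T=20)
    rate = report.pooled["misclassification_rate"]
    assert 0.0 <= rate <= 1.0
    # confusion-matrix identity on the per-fold level
    n_wrong = sum(e["misclassification_rate"] * e["n_test"] for e in report.per_fold)
    assert rate == pytest.approx(n_wrong / sim_dataset.n_samples)


def test_harf_on_single_class_matches_rf_report(tiny_dataset):
    one = dataset_from_arrays(tiny_dataset.features, tiny_dataset.responses,
                              np.ones(8, dtype=int))
    rf_rep = kfold_cv(one, "rf", k=2, seed=3, T=6, m=3, n_size=2,
                      rf_mode="leaf_means")
    harf_rep = kfold_cv(one, "harf", k=2, seed=3, T=6, m=3, n_size=2)
    assert harf_rep.pooled["mse"] == rf_rep.pooled["mse"]
    assert harf_rep.pooled["mae"] == rf_rep.pooled["mae"]


def test_cv_reproducible(sim_dataset):
    a = kfold_cv(sim_dataset, "harf", k=3, seed=8, T=10)
    b = kfold_cv(sim_dataset, "harf", k=3, seed=8, T=10)
    assert a.to_dict() == b.to_dict()


def test_one_hot_dataset_structure(sim_dataset):
    aug = one_hot_dataset(sim_dataset)
    K = sim_dataset.n_classes
    assert aug.n_features == sim_dataset.n_features + K
    indicators = aug.features[:, -K:]
    np.testing.assert_allclose(indicators.sum(axis=1), 1.0)
    assert set(np.unique(indicators).tolist()) <= {0.0, 1.0}


def test_one_hot_with_single_class_matches_plain_rf(tiny_dataset):
    one = dataset_from_arrays(tiny_dataset.features, tiny_dataset.responses,
                              np.ones(8, dtype=int))
    # with every feature in play the constant indicator column can never win
    # a split, so the augmented forest reproduces the plain one
    rep_plain = kfold_cv(one, "rf", k=2, seed=5, T=5, m=3, n_size=2)
    rep_hot = kfold_cv(one, "one_hot_rf", k=2, seed=5, T=5, m=4, n_size=2)
    assert rep_hot.pooled["mse"] == pytest.approx(rep_plain.pooled["mse"], abs=1e-12)


def test_one_hot_cv_runs_on_two_classes(sim_dataset):
    rep = kfold_cv(sim_dataset, "one_hot_rf", k=3, seed=2, T=10)
    assert rep.pooled["mse"] >= 0.0
    assert np.isnan(rep.pooled["misclassification_rate"])


def test_top_trees_identity_at_full_fraction(sim_dataset):
    r = top_trees_experiment(sim_dataset, top_frac=1.0, seed=6, T=20)
    assert r["mae_top_trees"] == pytest.approx(r["mae_all_trees"], abs=1e-12)
    again = top_trees_experiment(sim_dataset, top_frac=1.0, seed=6, T=20)
    assert r == again        # deterministic given seed
    with pytest.raises(ValueError):
        top_trees_experiment(sim_dataset, split=(0.5, 0.2, 0.2), seed=0, T=5)


def test_two_stage_c_with_perfect_hook_reduces_to_harf(tiny_dataset):
    one = dataset_from_arrays(tiny_dataset.features, tiny_dataset.responses,
                              np.ones(8, dtype=int))
    hook = lambda X, labels: (lambda Xq: np.ones(np.atleast_2d(Xq).shape[0], dtype=int))
    model = fit_two_stage(one, "C", classifier_hook=hook, T=6, m=3, n_size=2, seed=2)
    from harf.heterogeneity import harf_fit, harf_predict
    ref = harf_fit(one, T=6, m=3, n_size=2, seed=2)
    for x in one.features:
        c_ts, p_ts = model.predict(x)
        c_h, p_h = harf_predict(ref, x)
        assert c_ts == c_h
        np.testing.assert_array_equal(p_ts, p_h)


def test_two_stage_b_single_class_is_plain_forest_of_its_training_subset():
    rng = np.random.default_rng(12)
    ds = dataset_from_arrays(rng.normal(size=(16, 3)), rng.normal(size=16),
                             np.ones(16, dtype=int))
    hook = lambda X, labels: (lambda Xq: np.ones(np.atleast_2d(Xq).shape[0], dtype=int))
    model = fit_two_stage(ds, "B", classifier_hook=hook, T=5, m=2, n_size=3, seed=1)
    assert np.all(model.tree_categories == 1)    # every tree assigned the class
    x = ds.features[0]
    _, pred = model.predict(x)
    from harf.forest import forest_predict
    np.testing.assert_array_equal(
        pred, forest_predict(model.harf_model.forest, x, mode="leaf_means"))


def test_two_stage_cv_reports_misclassification(sim_dataset):
    rep = kfold_cv(sim_dataset, "two_stage_c", k=3, seed=0, T=10)
    assert 0.0 <= rep.pooled["misclassification_rate"] <= 1.0
    with pytest.raises(ValueError):
        fit_two_stage(sim_dataset, "Z")


def test_threshold_sweep_matches_default_at_half(sim_dataset):
    sweep = threshold_sweep(sim_dataset, [0.5], k=3, seed=9, T=10)
    default = kfold_cv(sim_dataset, "harf", k=3, seed=9, T=10)
    (thr, rep), = sweep
    assert thr == 0.5
    assert rep.pooled["mse"] == pytest.approx(default.pooled["mse"], abs=1e-12)
    assert rep.pooled["mae"] == pytest.approx(default.pooled["mae"], abs=1e-12)


def test_threshold_sweep_monotone_class1_calls(sim_dataset):
    grid = [0.45, 0.5, 0.55]
    results = threshold_sweep(sim_dataset, grid, k=3, seed=9, T=10)
    assert all(rep.pooled["mse"] >= 0 for _, rep in results)
    with pytest.raises(ValueError):
        one = dataset_from_arrays(sim_dataset.features,
                                  sim_dataset.responses,
                                  np.ones(sim_dataset.n_samples, dtype=int))
        threshold_sweep(one, grid, k=3, seed=0, T=5)


def test_unknown_model_spec_rejected(tiny_dataset):
    with pytest.raises(ValueError, match="unknown model spec"):
        kfold_cv(tiny_dataset, "gradient_unicorn", k=2, seed=0, T=2, m=2)
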