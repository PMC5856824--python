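"""Stratified CV, linear model, permutation null, and feature selection."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from tcd.classify import (
    CvConfig,
    compare_real_vs_null,
    evaluate_cv,
    permutation_null,
    selected_features,
    stratified_kfold,
    train_linear,
)


def test_stratification_worked_example():
    """100 subjects at 60/40 with k=10: every training split is exactly 54/36."""
    labels = np.array(["healthy"] * 60 + ["disorder"] * 40)
    fold = stratified_kfold(labels, k=10, seed=3)
    for f in range(10):
        train = labels[fold != f]
        assert np.sum(train == "healthy") == 54
        assert np.sum(train == "disorder") == 36


def test_stratified_kfold_errors_and_determinism():
    labels = np.array([0] * 6 + [1] * 6)
    with pytest.raises(ValueError):
        stratified_kfold(labels, k=1, seed=0)
    with pytest.raises(ValueError):
        stratified_kfold(labels, k=8, seed=0)  # class count < k
    np.testing.assert_array_equal(
        stratified_kfold(labels, 3, seed=5), stratified_kfold(labels, 3, seed=5)
    )


def test_stratification_proportions_property():
    rng = np.random.default_rng(0)
    labels = rng.choice(["a", "b"], p=[0.7, 0.3], size=200)
    fold = stratified_kfold(labels, 10, seed=1)
    global_prop = np.mean(labels == "a")
    for f in range(10):
        train = labels[fold != f]
        assert abs(np.mean(train == "a") - global_prop) < 0.02


def test_train_linear_separable():
    X = np.concatenate([-1 + 0.0 * np.arange(20), 1 + 0.0 * np.arange(20)])[:, None]
    y = np.array([0] * 20 + [1] * 20)
    model = train_linear(X, y)
    assert np.mean(model.predict(X) == y) == 1.0


def test_train_linear_constant_feature_dropped():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(40), rng.standard_normal(40)])
    y = np.array([0] * 25 + [1] * 15)
    model = train_linear(X, y)
    assert model.weights[0, 0] == pytest.approx(0.0, abs=1e-8)
    Xc = np.ones((10, 2))  # constant input -> prior-driven prediction
    assert np.all(model.predict(Xc) == model.predict(Xc)[0])


def test_train_linear_label_flip_negates_weights():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((60, 5))
    y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
    w1 = train_linear(X, y).weights
    w2 = train_linear(X, 1 - y).weights
    np.testing.assert_allclose(w1, -w2, atol=1e-6)


def test_train_linear_single_class_errors():
    with pytest.raises(ValueError):
        train_linear(np.zeros((5, 2)), np.zeros(5))


def test_evaluate_cv_separable_table(make_gaussian_table):
    table = make_gaussian_table({"healthy": 30, "tinnitus": 20}, seed=4, effect=4.0)
    rep = evaluate_cv(table, CvConfig(k=10, n_repeats=3, seed=0))
    assert rep.mean["accuracy"] > 0.98
    assert rep.mean["kappa"] > 0.95
    assert rep.mean["fpr"] < 0.05
    assert rep.mean["rmse"] >= rep.mean["mae"]


def test_evaluate_cv_chance_on_noise(make_gaussian_table):
    # average over independent noise datasets: a single dataset's CV score
    # fluctuates around its own dataset-level optimum, not around 0
    kappas = []
    for seed in range(5):
        table = make_gaussian_table({"healthy": 30, "tinnitus": 20}, seed=seed, effect=0.0)
        rep = evaluate_cv(table, CvConfig(k=5, n_repeats=4, seed=0))
        kappas.append(rep.mean["kappa"])
    assert -0.1 <= np.mean(kappas) <= 0.1


def test_permutation_null_deterministic_and_calibrated(make_gaussian_table):
    table = make_gaussian_table({"healthy": 30, "tinnitus": 20}, seed=6, effect=4.0)
    cfg = CvConfig(k=5, n_repeats=1, seed=0)
    null1 = permutation_null(table, cfg, n_perm=30, master_seed=9)
    null2 = permutation_null(table, cfg, n_perm=30, master_seed=9)
    assert null1.per_perm == null2.per_perm
    assert abs(null1.mean["kappa"]) < 0.06


def test_compare_real_vs_null_identities(make_gaussian_table):
    table = make_gaussian_table({"healthy": 20, "tinnitus": 15}, seed=7, effect=4.0)
    rep = evaluate_cv(table, CvConfig(k=5, n_repeats=5, seed=1))
    null = permutation_null(table, CvConfig(k=5, n_repeats=1, seed=1), n_perm=20, master_seed=2)
    res = compare_real_vs_null(rep, null, "accuracy")
    t = stats.ttest_ind(rep.metric_values("accuracy"), null.metric_values("accuracy")).statistic
    assert res["F"] == pytest.approx(t**2, rel=1e-8)
    assert res["p"] < 0.001  # separable real model vs chance null
    with pytest.raises(KeyError):
        compare_real_vs_null(rep, null, "f1")


def test_compare_identical_distributions_zero_F(make_gaussian_table):
    table = make_gaussian_table({"healthy": 20, "tinnitus": 15}, seed=8, effect=4.0)
    rep = evaluate_cv(table, CvConfig(k=5, n_repeats=4, seed=1))
    from tcd.classify import NullReport

    null = NullReport(rep.per_repeat, rep.mean, rep.sd, len(rep.per_repeat))
    assert compare_real_vs_null(rep, null, "kappa")["F"] == pytest.approx(0.0, abs=1e-12)


def test_selected_features_thresholding():
    class Fake:
        weights = np.array([[0.9, 0.01, 0.02]])
        feature_names = ("a", "b", "c")

    assert selected_features(Fake(), 0.25) == ["a"]
    Fake.weights = np.zeros((1, 3))
    assert selected_features(Fake()) == []


def test_selected_features_find_auditory_for_tinnitus(small_table):
    model = train_linear(small_table.data.to_numpy(), small_table.labels.to_numpy())
    picks = selected_features(model, threshold=0.25)
    assert any(name.startswith("AUD_") for name in picks)


def test_class_weighting_similar_accuracy_when_balanced(make_gaussian_table):
    table = make_gaussian_table({"healthy": 25, "tinnitus": 25}, seed=9, effect=2.0)
    acc_u = evaluate_cv(table, CvConfig(k=5, n_repeats=3, seed=0)).mean["accuracy"]
    acc_w = evaluate_cv(
        table, CvConfig(k=5, n_repeats=3, seed=0, class_weighting=True)
    ).mean["accuracy"]
    assert abs(acc_u - acc_w) <= 0.02
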