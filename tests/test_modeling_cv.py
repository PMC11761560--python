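import numpy as np
import pytest

from ergml.modeling_cv import (
    ConfusionMatrix,
    ModelSpec,
    assign_subject_folds,
    compute_metrics,
    cross_validate,
    run_experiment,
    smote_balance,
    tune_hyperparameters,
)


# ---------------------------------------------------------------------------
# SMOTE

def test_smote_balances_to_majority():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((14, 3))
    y = np.array(["A"] * 10 + ["B"] * 4)
    Xb, yb = smote_balance(X, y, seed=1)
    _, counts = np.unique(yb, return_counts=True)
    assert counts.tolist() == [10, 10]


def test_smote_rows_are_convex_combinations():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((16, 4))
    y = np.array(["A"] * 12 + ["B"] * 4)
    Xb, yb = smote_balance(X, y, seed=2)
    originals = X[y == "B"]
    synth = Xb[len(X):]
    assert (yb[len(X):] == "B").all()
    for z in synth:
        on_segment = False
        for i in range(len(originals)):
            for j in range(len(originals)):
                if i == j:
                    continue
                d = originals[j] - originals[i]
                denom = float(d @ d)
                if denom == 0:
                    continue
                u = float((z - originals[i]) @ d) / denom
                if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                    z, originals[i] + u * d, atol=1e-9
                ):
                    on_segment = True
                    break
            if on_segment:
                break
        assert on_segment


def test_smote_deterministic():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((12, 3))
    y = np.array(["A"] * 8 + ["B"] * 4)
    out1 = smote_balance(X, y, seed=5)
    out2 = smote_balance(X, y, seed=5)
    assert np.array_equal(out1[0], out2[0])


def test_smote_single_class_rejected():
    with pytest.raises(ValueError):
        smote_balance(np.zeros((5, 2)), np.array(["A"] * 5))


# ---------------------------------------------------------------------------
# metrics

def metric_oracle(tp, fn, fp, tn):
    """Independent brute-force metric arithmetic (guarded ratios)."""
    div = lambda a, b: a / b if b else 0.0
    precision = div(tp, tp + fp)
    recall = div(tp, tp + fn)
    specificity = div(tn, tn + fp)
    f1 = div(2 * precision * recall, precision + recall)
    ba = (recall + specificity) / 2
    return precision, recall, f1, specificity, ba


def test_metric_arithmetic_example():
    m = compute_metrics(ConfusionMatrix.from_counts(tp=8, fn=2, fp=3, tn=7))
    assert m.sensitivity == pytest.approx(0.8)
    assert m.specificity == pytest.approx(0.7)
    assert m.balanced_accuracy == pytest.approx(0.75)
    assert m.precision == pytest.approx(8 / 11)
    assert m.f1 == pytest.approx(2 * (8 / 11) * 0.8 / ((8 / 11) + 0.8))


def test_metrics_match_enumerated_oracle():
    for tp in range(4):
        for fn in range(4):
            for fp in range(4):
                for tn in range(4):
                    if tp + fn + fp + tn == 0:
                        continue
                    m = compute_metrics(ConfusionMatrix.from_counts(tp, fn, fp, tn))
                    p, r, f1, s, ba = metric_oracle(tp, fn, fp, tn)
                    assert m.precision == pytest.approx(p)
                    assert m.recall == pytest.approx(r)
                    assert m.f1 == pytest.approx(f1)
                    assert m.specificity == pytest.approx(s)
                    assert m.balanced_accuracy == pytest.approx(ba)


def test_perfect_classifier_all_ones():
    m = compute_metrics(ConfusionMatrix.from_counts(tp=5, fn=0, fp=0, tn=9))
    assert (m.precision, m.recall, m.f1, m.specificity, m.balanced_accuracy) == (
        1.0, 1.0, 1.0, 1.0, 1.0,
    )


def test_constant_predictor_has_chance_ba():
    """Predicting one class always: sensitivity 1, specificity 0, BA 0.5."""
    m = compute_metrics(ConfusionMatrix.from_counts(tp=30, fn=0, fp=70, tn=0))
    assert m.balanced_accuracy == 0.5


def test_multiclass_macro_recall():
    matrix = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]])
    m = compute_metrics(ConfusionMatrix(matrix=matrix, classes=("a", "b", "c")))
    assert m.balanced_accuracy == pytest.approx(0.8)


def test_all_zero_matrix_rejected():
    with pytest.raises(ValueError):
        compute_metrics(ConfusionMatrix(matrix=np.zeros((2, 2), dtype=int), classes=("a", "b")))


# ---------------------------------------------------------------------------
# folds / CV

def test_fold_assignment_partitions_subjects():
    rng = np.random.default_rng(0)
    for draw in range(200):
        n = int(rng.integers(24, 60))
        subjects = np.array([f"s{i}" for i in range(n)])
        labels = rng.choice(["x", "y"], size=n, p=[0.6, 0.4])
        if min((labels == "x").sum(), (labels == "y").sum()) < 2:
            continue
        assignment = assign_subject_folds(subjects, labels, k=5, seed=draw)
        assert set(assignment) == set(subjects)  # every subject in exactly one fold
        folds = np.array([assignment[s] for s in subjects])
        for f in np.unique(folds):
            assert not (set(subjects[folds == f]) & set(subjects[folds != f]))


def test_cross_validate_no_leakage_and_raw_test_distribution(make_gaussian_table):
    table = make_gaussian_table(n_per_class=25, p=5, seed=4)
    spec = ModelSpec("RF", grid={"n_estimators": [50]}, seed=0)
    res = cross_validate(spec, table, k=5)
    folds = np.array([res.fold_assignment[s] for s in table.features.index])
    # test folds together reproduce the raw (un-SMOTEd) cohort exactly
    test_labels = [table.labels.iloc[i] for f in np.unique(folds) for i in np.where(folds == f)[0]]
    assert sorted(test_labels) == sorted(table.labels)
    assert all(0.0 <= m.balanced_accuracy <= 1.0 for m in res.fold_metrics)
    assert 0.0 <= res.pooled.balanced_accuracy <= 1.0
    assert res.pooled.auc is not None and 0.0 <= res.pooled.auc <= 1.0


def test_permuted_labels_score_at_chance(make_gaussian_table):
    """Destroying the label-feature link drives CV BA to 0.5 on average."""
    bas = []
    for seed in range(20):
        table = make_gaussian_table(n_per_class=30, p=6, shift=2.0, seed=seed)
        rng = np.random.default_rng(seed)
        permuted = table.labels.copy()
        permuted[:] = rng.permutation(permuted.to_numpy())
        table.labels = permuted
        table.meta["group"] = permuted
        spec = ModelSpec("KNN", grid={"n_neighbors": [5]}, seed=seed)
        bas.append(cross_validate(spec, table, k=5, seed=seed).pooled.balanced_accuracy)
    assert 0.42 <= float(np.mean(bas)) <= 0.58


def test_tuning_single_point_grid(make_gaussian_table):
    table = make_gaussian_table(seed=5)
    spec = ModelSpec("KNN", grid={"n_neighbors": [7]}, seed=0)
    assert tune_hyperparameters(spec, table) == {"n_neighbors": 7}


def test_tuning_deterministic(make_gaussian_table):
    table = make_gaussian_table(n_per_class=20, p=5, seed=6)
    spec = ModelSpec("KNN", grid={"n_neighbors": [3, 5, 7]}, seed=11)
    assert tune_hyperparameters(spec, table) == tune_hyperparameters(spec, table)


def test_separable_data_favours_small_k(make_gaussian_table):
    wins = 0
    for seed in range(10):
        table = make_gaussian_table(n_per_class=30, p=4, shift=3.0, seed=seed)
        spec = ModelSpec("KNN", grid={"n_neighbors": [3, 5, 7, 9, 11]}, seed=seed)
        if tune_hyperparameters(spec, table)["n_neighbors"] <= 7:
            wins += 1
    assert wins >= 7


def test_run_experiment_grid(make_gaussian_table):
    """One row per technique x fusion, plus two refinement rows per fusion."""
    tables = {
        "A": make_gaussian_table(n_per_class=16, p=5, shift=2.0, seed=0),
        "B": make_gaussian_table(n_per_class=16, p=5, shift=1.0, seed=1),
    }
    specs = [
        ModelSpec("RF", grid={"n_estimators": [30]}, seed=0),
        ModelSpec("KNN", grid={"n_neighbors": [3]}, seed=0),
        ModelSpec("XGB", grid={"n_estimators": [30]}, seed=0),
    ]
    df = run_experiment(tables, specs, k=3, seed=0)
    base = df[df["selection"] == "none"]
    assert len(base) == 6
    assert base.groupby("fusion")["best"].sum().tolist() == [1, 1]
    refined = df[df["selection"] != "none"]
    assert len(refined) == 4
    for _, row in refined.iterrows():
        assert row["n_features"] <= 5
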