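"""Classifier training and subject-wise evaluation.

The evaluation protocol has three stages: (1) a fused feature table is
built; (2) hyperparameters are tuned by 3-fold subject-wise cross-validation
with SMOTE balancing of each training fold and relative-threshold
random-forest feature selection; (3) the tuned model is evaluated by 10-fold
subject-wise cross-validation, again with SMOTE applied to training folds
only — test folds keep the raw class distribution.  Folds are assigned at
the subject level so no individual contributes to both train and test.

Metrics: precision = TP/(TP+FP), recall = sensitivity = TP/(TP+FN),
F1 = harmonic mean of precision and recall, specificity = TN/(TN+FP), and
balanced accuracy = (sensitivity + specificity)/2 for two classes or the
macro mean of per-class recalls otherwise.  AUC is the ROC area
(macro one-vs-rest for more than two classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ergml.fusion_selection import FeatureTable, SelectionResult, fi_select

__all__ = [
    "TECHNIQUES",
    "ModelSpec",
    "ConfusionMatrix",
    "Metrics",
    "CVResult",
    "make_model",
    "smote_balance",
    "assign_subject_folds",
    "tune_hyperparameters",
    "cross_validate",
    "compute_metrics",
    "run_experiment",
]

TECHNIQUES = ("RF", "AdaB", "GradB", "XGB", "SVM", "KNN", "MLP")

#: compact default grids; the study protocol defines the tuning procedure
#: but not the grids, so these cover the usual capacity knobs per family
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [200], "max_depth": [None, 5]},
    "AdaB": {"n_estimators": [50, 100]},
    "GradB": {"n_estimators": [100], "max_depth": [2, 3]},
    "XGB": {"n_estimators": [100], "max_depth": [3, 5]},
    "SVM": {"C": [1.0, 10.0]},
    "KNN": {"n_neighbors": [3, 5, 7]},
    "MLP": {"hidden_layer_sizes": [(32,)], "alpha": [1e-3, 1e-1]},
}


@dataclass
class ModelSpec:
    technique: str
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.technique].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, vals)) for vals in product(*(self.grid[k] for k in keys))]


class _LabelEncodedXGB:
    """Adapter giving the XGBoost classifier a string-label interface."""

    def __init__(self, model: XGBClassifier):
        self._model = model

    def fit(self, X, y):
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self._model.fit(X, y_enc)
        return self

    def predict(self, X):
        return self.classes_[self._model.predict(X)]

    def predict_proba(self, X):
        return self._model.predict_proba(X)


def make_model(technique: str, params: dict | None = None, seed: int = 0):
    """Instantiate a classifier; kernel/distance models are wrapped with a
    standardising pipeline (their metrics are scale-sensitive; trees are not)."""
    params = params or {}
    if technique == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if technique == "AdaB":
        return AdaBoostClassifier(random_state=seed, **params)
    if technique == "GradB":
        return GradientBoostingClassifier(random_state=seed, **params)
    if technique == "XGB":
        return _LabelEncodedXGB(
            XGBClassifier(
                random_state=seed, eval_metric="logloss", n_jobs=1, verbosity=0,
                **params,
            )
        )
    if technique == "SVM":
        clf = SVC(probability=True, random_state=seed, **params)
    elif technique == "KNN":
        clf = KNeighborsClassifier(**params)
    elif technique == "MLP":
        clf = MLPClassifier(random_state=seed, max_iter=800, **params)
    else:
        raise ValueError(f"unknown technique {technique!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# SMOTE

def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: upsample every class to the majority
    count by interpolating between same-class nearest neighbours.

    Each synthetic row is ``x + u * (neighbour - x)`` with u ~ U(0,1), so it
    lies on the segment between two original same-class rows.  If a minority
    class has fewer than ``k_neighbors + 1`` members, k is reduced with a
    warning.  Applied to training folds only — never to test data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires at least two classes")
    n_target = counts.max()
    rng = np.random.default_rng(seed)

    X_out, y_out = [X], [y]
    for cls, count in zip(classes, counts):
        deficit = n_target - count
        if deficit == 0:
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, count - 1)
        if k < 1:
            warnings.warn(f"class {cls!r} has a single member; duplicating it")
            X_out.append(np.repeat(Xc, deficit, axis=0))
            y_out.append(np.full(deficit, cls, dtype=y.dtype))
            continue
        if k < k_neighbors:
            warnings.warn(
                f"class {cls!r} has only {count} members; k reduced from "
                f"{k_neighbors} to {k}"
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, nbr = nn.kneighbors(Xc)  # first column is the point itself
        base_idx = rng.integers(0, count, size=deficit)
        nbr_pick = nbr[base_idx, rng.integers(1, k + 1, size=deficit)]
        u = rng.random(deficit)[:, None]
        synth = Xc[base_idx] + u * (Xc[nbr_pick] - Xc[base_idx])
        X_out.append(synth)
        y_out.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


# ---------------------------------------------------------------------------
# folds

def assign_subject_folds(
    subjects: np.ndarray, labels: np.ndarray, k: int, seed: int = 0
) -> dict[str, int]:
    """Stratified subject-level fold assignment.

    Unique subjects are shuffled within each class and dealt round-robin
    into k folds, so folds are class-stratified and every subject lands in
    exactly one test fold.  If a class has fewer subjects than k, k is
    reduced for the whole split with a warning.
    """
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    _, first_idx = np.unique(subjects, return_index=True)
    uniq_subj = subjects[np.sort(first_idx)]
    subj_label = {s: labels[subjects == s][0] for s in uniq_subj}

    min_class = min(np.sum([lbl == c for lbl in subj_label.values()]) for c in set(subj_label.values()))
    if min_class < k:
        warnings.warn(f"smallest class has {min_class} subjects; k reduced from {k}")
        k = max(int(min_class), 2)

    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for cls in sorted(set(subj_label.values())):
        members = [s for s in uniq_subj if subj_label[s] == cls]
        rng.shuffle(members)
        for i, s in enumerate(members):
            assignment[s] = (i + offset) % k
        offset += len(members)  # stagger classes across folds
    return assignment


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionMatrix:
    """k x k confusion matrix; rows = true class, columns = predicted."""

    matrix: np.ndarray
    classes: tuple

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes) -> "ConfusionMatrix":
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        m = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            m[index[t], index[p]] += 1
        return cls(matrix=m, classes=classes)

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, tn: int) -> "ConfusionMatrix":
        """Binary matrix from one-vs-rest counts (positive class last)."""
        return cls(matrix=np.array([[tn, fp], [fn, tp]]), classes=("neg", "pos"))

    def ovr_counts(self, class_index: int) -> tuple[int, int, int, int]:
        m = self.matrix
        tp = int(m[class_index, class_index])
        fn = int(m[class_index].sum() - tp)
        fp = int(m[:, class_index].sum() - tp)
        tn = int(m.sum() - tp - fn - fp)
        return tp, fn, fp, tn


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
        }


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Precision/recall/F1/sensitivity/specificity/BA from a confusion matrix.

    Two classes use the one-vs-rest counts of the positive (last) class;
    more classes use macro averaging, with balanced accuracy the macro mean
    of per-class recalls.  Zero-denominator ratios evaluate to 0 and set the
    degenerate flag.
    """
    if cm.matrix.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    k = len(cm.classes)
    degenerate = False
    if k == 2:
        tp, fn, fp, tn = cm.ovr_counts(1)
        precision, d1 = _safe_div(tp, tp + fp)
        recall, d2 = _safe_div(tp, tp + fn)
        specificity, d3 = _safe_div(tn, tn + fp)
        f1, d4 = _safe_div(2 * precision * recall, precision + recall)
        ba = (recall + specificity) / 2.0
        degenerate = d1 or d2 or d3 or d4
        return Metrics(precision, recall, f1, recall, specificity, ba, degenerate=degenerate)

    precisions, recalls, f1s, specs = [], [], [], []
    for ci in range(k):
        tp, fn, fp, tn = cm.ovr_counts(ci)
        p, d1 = _safe_div(tp, tp + fp)
        r, d2 = _safe_div(tp, tp + fn)
        s, d3 = _safe_div(tn, tn + fp)
        f, d4 = _safe_div(2 * p * r, p + r)
        degenerate |= d1 or d2 or d3 or d4
        precisions.append(p); recalls.append(r); f1s.append(f); specs.append(s)
    ba = float(np.mean(recalls))
    return Metrics(
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        sensitivity=float(np.mean(recalls)),
        specificity=float(np.mean(specs)),
        balanced_accuracy=ba,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# tuning and evaluation

@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    fold_confusions: list[ConfusionMatrix]
    pooled: Metrics
    fold_assignment: dict[str, int]
    chosen_params: dict
    kept_features: tuple[str, ...]
    flagged_folds: list[int] = field(default_factory=list)

    @property
    def balanced_accuracy(self) -> float:
        return self.pooled.balanced_accuracy


def tune_hyperparameters(spec: ModelSpec, table: FeatureTable, seed: int | None = None) -> dict:
    """Choose the grid point maximising mean 3-fold subject-wise balanced
    accuracy, with per-fold SMOTE and relative-FI feature selection."""
    seed = spec.seed if seed is None else seed
    points = spec.grid_points()
    if len(points) == 1:
        return points[0]

    X_df, y = table.features, table.labels.to_numpy()
    subjects = table.features.index.to_numpy()
    assignment = assign_subject_folds(subjects, y, k=3, seed=seed)
    fold_ids = np.array([assignment[s] for s in subjects])

    best_point, best_score = None, -np.inf
    for point in points:
        scores = []
        for f in sorted(set(fold_ids)):
            tr, te = fold_ids != f, fold_ids == f
            sub = FeatureTable(X_df.loc[tr], table.labels.loc[tr], table.meta.loc[tr])
            sel = fi_select(sub, seed=seed, n_estimators=100)
            cols = list(sel.kept_features)
            Xb, yb = smote_balance(X_df.loc[tr, cols].to_numpy(), y[tr], seed=seed)
            model = make_model(spec.technique, point, seed=seed)
            model.fit(Xb, yb)
            pred = model.predict(X_df.loc[te, cols].to_numpy())
            cm = ConfusionMatrix.from_predictions(y[te], pred, np.unique(y))
            scores.append(compute_metrics(cm).balanced_accuracy)
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_point, best_score = point, mean_score
    if best_point is None:
        raise RuntimeError("hyperparameter grid exhausted with no valid score")
    return best_point


def cross_validate(
    spec: ModelSpec,
    table: FeatureTable,
    k: int = 10,
    selection: SelectionResult | None = None,
    params: dict | None = None,
    seed: int | None = None,
) -> CVResult:
    """k-fold subject-wise evaluation with train-only SMOTE.

    ``selection`` restricts the table to its kept features before training;
    ``params`` fixes the hyperparameters (otherwise the first grid point is
    used).  Folds where a class is absent from the test split are flagged;
    their predictions still enter the pooled confusion matrix.
    """
    seed = spec.seed if seed is None else seed
    if selection is not None:
        table = table.subset_features(list(selection.kept_features))
    params = params or spec.grid_points()[0]

    X_df, y = table.features, table.labels.to_numpy()
    subjects = table.features.index.to_numpy()
    classes = tuple(np.unique(y))
    assignment = assign_subject_folds(subjects, y, k=k, seed=seed)
    fold_ids = np.array([assignment[s] for s in subjects])

    fold_metrics, fold_cms, flagged = [], [], []
    all_true, all_pred, all_scores = [], [], []
    for f in sorted(set(fold_ids)):
        tr, te = fold_ids != f, fold_ids == f
        assert not (set(subjects[tr]) & set(subjects[te])), "subject leakage across folds"
        Xb, yb = smote_balance(X_df.loc[tr].to_numpy(), y[tr], seed=seed + f)
        model = make_model(spec.technique, params, seed=seed)
        model.fit(Xb, yb)
        X_te = X_df.loc[te].to_numpy()
        pred = model.predict(X_te)
        proba = model.predict_proba(X_te) if hasattr(model, "predict_proba") else None

        cm = ConfusionMatrix.from_predictions(y[te], pred, classes)
        fold_cms.append(cm)
        if set(np.unique(y[te])) != set(classes):
            flagged.append(int(f))
        else:
            fold_metrics.append(compute_metrics(cm))
        all_true.append(y[te]); all_pred.append(pred)
        if proba is not None:
            all_scores.append(proba)

    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    pooled_cm = ConfusionMatrix.from_predictions(y_true, y_pred, classes)
    pooled = compute_metrics(pooled_cm)
    if all_scores:
        scores = np.vstack(all_scores)
        try:
            if len(classes) == 2:
                pooled.auc = float(roc_auc_score(y_true == classes[1], scores[:, 1]))
            else:
                pooled.auc = float(
                    roc_auc_score(y_true, scores, multi_class="ovr", average="macro",
                                  labels=list(classes))
                )
        except ValueError:
            pooled.auc = None

    return CVResult(
        fold_metrics=fold_metrics,
        fold_confusions=fold_cms,
        pooled=pooled,
        fold_assignment=assignment,
        chosen_params=params,
        kept_features=tuple(table.feature_names),
        flagged_folds=flagged,
    )


def run_experiment(
    tables: dict[str, FeatureTable],
    model_specs: list[ModelSpec],
    k: int = 10,
    seed: int = 0,
    refine: bool = True,
) -> pd.DataFrame:
    """Evaluate every (technique x fused table) combination.

    Each combination is tuned (3-fold) then evaluated (k-fold).  With
    ``refine=True`` the best row of each fused table is re-run twice with
    the stricter selections (FI >= 0.01 and Shapley >= 0.005) applied before
    evaluation.  Returns a tidy results table.
    """
    from ergml.fusion_selection import shapley_select

    rows = []
    for name, table in tables.items():
        for spec in model_specs:
            params = tune_hyperparameters(spec, table, seed=seed)
            res = cross_validate(spec, table, k=k, params=params, seed=seed)
            rows.append(
                {
                    "fusion": name, "technique": spec.technique, "selection": "none",
                    "n_features": len(res.kept_features),
                    "balanced_accuracy": res.pooled.balanced_accuracy,
                    "f1": res.pooled.f1, "auc": res.pooled.auc,
                    "params": params, "best": False,
                }
            )
    df = pd.DataFrame(rows)

    if refine:
        refined = []
        for name, table in tables.items():
            block = df[df["fusion"] == name]
            best = block.loc[block["balanced_accuracy"].idxmax()]
            df.loc[best.name, "best"] = True
            spec = next(s for s in model_specs if s.technique == best["technique"])
            params = best["params"]

            sel_fi = fi_select(table, mode="absolute_0.01", seed=seed)
            res_fi = cross_validate(spec, table, k=k, selection=sel_fi, params=params, seed=seed)

            Xb, yb = smote_balance(table.features.to_numpy(), table.labels.to_numpy(), seed=seed)
            model = make_model(spec.technique, params, seed=seed)
            model.fit(Xb, yb)
            sel_sh = shapley_select(model, table, seed=seed)
            res_sh = cross_validate(spec, table, k=k, selection=sel_sh, params=params, seed=seed)

            for sel_name, res in (("FI>=0.01", res_fi), ("Shapley>=0.005", res_sh)):
                refined.append(
                    {
                        "fusion": name, "technique": spec.technique, "selection": sel_name,
                        "n_features": len(res.kept_features),
                        "balanced_accuracy": res.pooled.balanced_accuracy,
                        "f1": res.pooled.f1, "auc": res.pooled.auc,
                        "params": params, "best": False,
                    }
                )
        df = pd.concat([df, pd.DataFrame(refined)], ignore_index=True)
    return df
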