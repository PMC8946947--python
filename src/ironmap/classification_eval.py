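"""Pairwise disease classification harness.

Per repeat: stratified 7:3 train/test split, z-score standardization fit on
the training rows only, Fisher top-k feature selection on the training rows
only, 3-fold cross-validated hyperparameter tuning per classifier, refit on
the full training set, and the metric suite (AUC, balanced accuracy,
sensitivity, specificity, accuracy) on both the out-of-fold training
predictions and the held-out test set. Metrics are averaged over repeats
(default 100). The first disease of a pair is the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_predict,
    train_test_split,
)
from sklearn.decomposition import PCA
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import FeatureTable, fisher_score, select_top_k

__all__ = [
    "CLASSIFIER_ROSTER",
    "SplitSpec",
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "make_split",
    "compute_metrics",
    "roc_auc",
    "run_task",
    "make_classifier",
    "DISEASE_PAIRS",
]

#: the six pairwise tasks over the four diagnostic groups
DISEASE_PAIRS = (
    ("MSA-P", "MSA-C"),
    ("MSA-P", "PD"),
    ("MSA-P", "PSP"),
    ("MSA-C", "PD"),
    ("MSA-C", "PSP"),
    ("PD", "PSP"),
)

#: classifier name -> (factory, hyperparameter grid)
CLASSIFIER_ROSTER: dict[str, tuple] = {
    "kNN": (lambda seed: KNeighborsClassifier(), {"n_neighbors": [3, 5]}),
    "linSVC": (lambda seed: SVC(kernel="linear", random_state=seed), {"C": [0.1, 1.0]}),
    "RBFSVC": (
        lambda seed: SVC(kernel="rbf", gamma="scale", random_state=seed),
        {"C": [1.0, 10.0]},
    ),
    "GP": (lambda seed: GaussianProcessClassifier(random_state=seed), {}),
    "RF": (
        lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
        {"max_depth": [None, 5]},
    ),
    "DT": (
        lambda seed: DecisionTreeClassifier(random_state=seed),
        {"max_depth": [None, 5]},
    ),
    "MLP": (
        lambda seed: MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=1000, random_state=seed
        ),
        {"alpha": [1e-3]},
    ),
    "ADA": (lambda seed: AdaBoostClassifier(random_state=seed), {"n_estimators": [50]}),
    "GNB": (lambda seed: GaussianNB(), {}),
    # a low-rank projection keeps the per-class covariances full rank at the
    # small per-fold class sizes of this cohort scale
    "QDA": (
        lambda seed: Pipeline(
            [("pca", PCA(n_components=5)),
             ("qda", QuadraticDiscriminantAnalysis())]
        ),
        {"qda__reg_param": [0.1]},
    ),
}


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has a zero denominator."""


@dataclass(frozen=True)
class SplitSpec:
    train: list
    test: list
    seed: int
    ratio: float = 0.7
    stratified: bool = True

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test overlap")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def make_split(
    table: FeatureTable, seed: int, ratio: float = 0.7, stratified: bool = True
) -> SplitSpec:
    """Stratified random train/test partition, deterministic per seed."""
    counts = table.labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 subjects to stratify: {dict(counts)}")
    subjects = list(table.matrix.index)
    train, test = train_test_split(
        subjects,
        train_size=ratio,
        random_state=seed,
        stratify=table.labels.to_numpy() if stratified else None,
        shuffle=True,
    )
    return SplitSpec(list(train), list(test), seed, ratio, stratified)


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, balanced accuracy, and accuracy.

    Raises :class:`UndefinedMetricError` on a zero denominator instead of
    silently returning 0.
    """
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no actual positives: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no actual negatives: specificity undefined")
    sen = c.tp / (c.tp + c.fn)
    spe = c.tn / (c.tn + c.fp)
    return {
        "Sen": sen,
        "Spe": spe,
        "bAcc": (sen + spe) / 2.0,
        "Acc": (c.tp + c.tn) / c.total,
    }


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney U equivalence.

    ``labels`` are 0/1 (or boolean); ties in ``scores`` contribute half.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def make_classifier(name: str, seed: int):
    """Instantiate one roster classifier with its hyperparameter grid."""
    if name not in CLASSIFIER_ROSTER:
        raise KeyError(f"unknown classifier {name!r}; roster: {list(CLASSIFIER_ROSTER)}")
    factory, grid = CLASSIFIER_ROSTER[name]
    return factory(seed), grid


def _decision_scores(est, x) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(x))
    return np.asarray(est.predict_proba(x))[:, 1]


@dataclass
class MetricsReport:
    """Per-repeat and averaged metrics for one task/classifier."""

    task: tuple[str, str]
    classifier: str
    per_repeat: pd.DataFrame  # columns: repeat, split, metric, value
    selected_features: list[list[str]] = field(default_factory=list)

    def mean(self, split: str, metric: str) -> float:
        rows = self.per_repeat.query("split == @split and metric == @metric")
        return float(rows["value"].mean())

    def summary(self) -> pd.DataFrame:
        grouped = (
            self.per_repeat.groupby(["split", "metric"])["value"]
            .agg(["mean", "std"])
            .reset_index()
        )
        grouped.insert(0, "classifier", self.classifier)
        grouped.insert(0, "task", f"{self.task[0]} vs {self.task[1]}")
        return grouped


def _evaluate_repeat(
    table: FeatureTable,
    positive: str,
    classifier: str,
    seed: int,
    k_features: int,
    tune: bool,
    max_redraws: int = 20,
):
    """One split/select/tune/fit/score cycle; redraws on degenerate folds."""
    for attempt in range(max_redraws):
        split = make_split(table, seed + 1000 * attempt)
        train = table.restrict(split.train)
        if train.labels.value_counts().min() >= 3:
            break
        warnings.warn(f"degenerate fold at seed {seed}; redrawing", stacklevel=2)
    else:
        raise RuntimeError("could not draw a split with >= 3 subjects per class")
    test = table.restrict(split.test)

    ranking = fisher_score(train)
    selected = select_top_k(ranking, k_features)

    scaler = StandardScaler().fit(train.matrix[selected].to_numpy())
    x_train = scaler.transform(train.matrix[selected].to_numpy())
    x_test = scaler.transform(test.matrix[selected].to_numpy())
    y_train = (train.labels == positive).to_numpy().astype(int)
    y_test = (test.labels == positive).to_numpy().astype(int)

    est, grid = make_classifier(classifier, seed)
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    if tune and grid:
        search = GridSearchCV(est, grid, cv=cv, scoring="roc_auc", refit=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(x_train, y_train)
        best = search.best_estimator_
    else:
        best = est
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best.fit(x_train, y_train)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # out-of-fold training predictions with the chosen hyperparameters
        method = "decision_function" if hasattr(best, "decision_function") else "predict_proba"
        oof_scores = cross_val_predict(best, x_train, y_train, cv=cv, method=method)
        if oof_scores.ndim > 1:
            oof_scores = oof_scores[:, 1]
        oof_pred = cross_val_predict(best, x_train, y_train, cv=cv, method="predict")
        best.fit(x_train, y_train)

    rows = []
    for split_name, y_true, y_pred, y_score in (
        ("train", y_train, oof_pred, oof_scores),
        ("test", y_test, best.predict(x_test), _decision_scores(best, x_test)),
    ):
        counts = ConfusionCounts(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        )
        metrics = compute_metrics(counts)
        metrics["AUC"] = roc_auc(y_score, y_true)
        rows.extend(
            {"split": split_name, "metric": k, "value": v} for k, v in metrics.items()
        )
    return rows, selected


def run_task(
    table: FeatureTable,
    pair: tuple[str, str],
    classifiers: tuple[str, ...] | None = None,
    n_repeats: int = 100,
    k_features: int = 10,
    master_seed: int = 0,
    tune: bool = True,
) -> dict[str, MetricsReport]:
    """Full repeated evaluation of one disease pair.

    Returns one :class:`MetricsReport` per classifier. Repeat r uses seed
    ``master_seed + r``; the same master seed reproduces the report exactly.
    """
    if pair[0] == pair[1]:
        raise ValueError("pair must name two distinct classes")
    sub = table.pair(*pair)
    present = set(sub.labels.unique())
    if present != set(pair):
        raise ValueError(f"table lacks classes {set(pair) - present}")
    classifiers = tuple(classifiers or CLASSIFIER_ROSTER)
    if k_features > sub.matrix.shape[1]:
        raise ValueError("k_features exceeds the number of features")

    reports: dict[str, MetricsReport] = {}
    for name in classifiers:
        all_rows = []
        all_selected = []
        for r in range(n_repeats):
            rows, selected = _evaluate_repeat(
                sub, pair[0], name, master_seed + r, k_features, tune
            )
            for row in rows:
                row["repeat"] = r
            all_rows.extend(rows)
            all_selected.append(selected)
        reports[name] = MetricsReport(
            task=pair,
            classifier=name,
            per_repeat=pd.DataFrame(all_rows),
            selected_features=all_selected,
        )
    return reports
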