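"""Random-forest feature ranking and kNN subtype classification.

A 200-tree random forest (fixed seed 42 by default) scores each feature
by impurity-based importance; the top-k features (default up to 40) feed
a k = 7 nearest-neighbors classifier.  Features are z-scored with
train-set statistics before distance computation.  Performance is
reported both on a stratified holdout split (accuracy, precision,
recall, F1, ROC AUC, positive class = 1 = SCC) and as stratified 5-fold
cross-validated accuracy; splits can optionally be grouped by patient so
no patient's images straddle train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ImportanceRanking",
    "ClassificationReport",
    "rank_features",
    "select_top",
    "knn_scores",
    "roc_auc",
    "evaluate",
]


@dataclass(frozen=True)
class ImportanceRanking:
    """Feature-importance scores from the random forest."""

    scores: dict[str, float]
    n_trees: int
    seed: int

    @property
    def order(self) -> list[str]:
        """Features by descending importance; ties broken lexicographically."""
        return sorted(self.scores, key=lambda k: (-self.scores[k], k))


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    cv_accuracy: float
    feature_subset: tuple[str, ...]
    knn_k: int
    split_seed: int
    grouping: str
    confusion: tuple[tuple[int, int], tuple[int, int]]  # [[tn, fp], [fn, tp]]

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "cv_accuracy": self.cv_accuracy,
            "knn_k": self.knn_k,
            "split_seed": self.split_seed,
            "grouping": self.grouping,
            "confusion": [list(r) for r in self.confusion],
            "feature_subset": list(self.feature_subset),
        }
        return d


def _validate_table(table: pd.DataFrame, labels: np.ndarray) -> None:
    bad = [c for c in table.columns if not np.all(np.isfinite(table[c].to_numpy(float)))]
    if bad:
        raise ValueError(f"non-finite feature columns: {bad}")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")


def rank_features(
    table: pd.DataFrame,
    labels,
    n_trees: int = 200,
    seed: int = 42,
) -> ImportanceRanking:
    """Impurity-based importances from a random forest.

    Deterministic given (table, labels, seed); importances sum to 1.
    """
    labels = np.asarray(labels)
    _validate_table(table, labels)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(table.to_numpy(float), labels)
    scores = dict(zip(table.columns, forest.feature_importances_))
    return ImportanceRanking(scores=scores, n_trees=n_trees, seed=seed)


def select_top(ranking: ImportanceRanking, k_max: int = 40) -> list[str]:
    """Top-min(k_max, available) feature names by importance."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return ranking.order[:k_max]


def select_above_mean(ranking: ImportanceRanking) -> list[str]:
    """Alternative cutoff: features with importance >= the mean importance."""
    thr = float(np.mean(list(ranking.scores.values())))
    return [f for f in ranking.order if ranking.scores[f] >= thr]


def knn_scores(
    train: pd.DataFrame,
    train_labels,
    test: pd.DataFrame,
    k: int = 7,
) -> np.ndarray:
    """Fraction of the k Euclidean-nearest train neighbors labeled 1.

    Features are standardized with train-set mean/sd before distances;
    predicted class is 1 when the score exceeds 0.5 (k = 7 is odd, so
    majority votes never tie).
    """
    train_labels = np.asarray(train_labels)
    if k > len(train):
        raise ValueError(f"k={k} exceeds train size {len(train)}")
    model = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
    model.fit(train.to_numpy(float), train_labels)
    proba = model.predict_proba(test.to_numpy(float))
    pos_col = list(model.classes_).index(1) if 1 in model.classes_ else None
    if pos_col is None:
        raise ValueError("train labels contain no positive (SCC = 1) sample")
    return proba[:, pos_col]


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative
    (ties counted 1/2); equals trapezoidal ROC area."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _holdout_split(labels, groups, holdout_fraction, seed):
    idx = np.arange(len(labels))
    if groups is None:
        return train_test_split(
            idx, test_size=holdout_fraction, stratify=labels, random_state=seed
        )
    # stratify at the patient level (each patient carries one label) so the
    # grouped holdout keeps both classes on both sides
    uniq, first = np.unique(groups, return_index=True)
    grp_labels = labels[first]
    tr_g, te_g = train_test_split(
        uniq, test_size=holdout_fraction, stratify=grp_labels, random_state=seed
    )
    return idx[np.isin(groups, tr_g)], idx[np.isin(groups, te_g)]


def evaluate(
    table: pd.DataFrame,
    labels,
    subset: list[str] | None = None,
    k: int = 7,
    holdout_fraction: float = 0.25,
    split_seed: int = 42,
    grouping: str = "image",
    groups=None,
) -> ClassificationReport:
    """Holdout metrics plus stratified 5-fold CV accuracy for one feature set.

    ``grouping="patient"`` (with ``groups`` = patient ids) keeps all
    images of a patient on the same side of every split.
    """
    labels = np.asarray(labels)
    if subset is None:
        subset = list(table.columns)
    missing = [c for c in subset if c not in table.columns]
    if missing:
        raise ValueError(f"subset names not in table: {missing}")
    X = table[subset]
    _validate_table(X, labels)
    if grouping not in ("image", "patient"):
        raise ValueError("grouping must be 'image' or 'patient'")
    grp = np.asarray(groups) if grouping == "patient" else None
    if grouping == "patient" and grp is None:
        raise ValueError("patient grouping requires the groups argument")

    tr, te = _holdout_split(labels, grp, holdout_fraction, split_seed)
    if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
        raise ValueError(
            "holdout split left a single class on one side; "
            "lower holdout_fraction or use more samples per class"
        )
    scores = knn_scores(X.iloc[tr], labels[tr], X.iloc[te], k=k)
    pred = (scores > 0.5).astype(int)
    truth = labels[te]
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    accuracy = (tp + tn) / len(truth)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    auc = roc_auc(scores, truth)

    if grp is None:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=split_seed)
        folds = cv.split(X, labels)
    else:
        cv = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=split_seed)
        folds = cv.split(X, labels, grp)
    fold_acc = []
    for ftr, fte in folds:
        if len(np.unique(labels[ftr])) < 2 or len(np.unique(labels[fte])) < 2:
            raise ValueError(
                "a CV fold contains a single class; re-stratify with more "
                "samples per class or fewer folds"
            )
        s = knn_scores(X.iloc[ftr], labels[ftr], X.iloc[fte], k=min(k, len(ftr)))
        fold_acc.append(float(np.mean((s > 0.5).astype(int) == labels[fte])))

    return ClassificationReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        auc=float(auc),
        cv_accuracy=float(np.mean(fold_acc)),
        feature_subset=tuple(subset),
        knn_k=k,
        split_seed=split_seed,
        grouping=grouping,
        confusion=((tn, fp), (fn, tp)),
    )
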