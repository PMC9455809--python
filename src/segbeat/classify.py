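"""Class-balanced random forest on selected beat features + segment labels,
AAMI class grouping, inter-patient evaluation and LOPO tuning.

The beat classifier is a bagged forest of ``n_d`` Gini-split decision trees
(default 200) with per-split candidate subsets of size floor(sqrt(m)) and
balanced per-sample weights (weight of class c = N_total / (C * N_c)).
Mutual-information feature selection runs on training records only; the
encoded segment-label columns bypass selection and are always appended.
Evaluation follows the inter-patient paradigm: train and test record sets
are disjoint, enforced with a hard leakage guard.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, mi_rank, select_top
from .segment import SEGMENT_FEATURE_PREFIX

# AAMI EC57 grouping of the 15 MIT-BIH beat symbols into 5 classes
AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "SVEB", "a": "SVEB", "J": "SVEB", "S": "SVEB",
    "V": "VEB", "E": "VEB",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}
AAMI_CLASSES = ("N", "SVEB", "VEB", "F", "Q")

# Standard inter-patient division of the MIT-BIH Arrhythmia records
# (paced records 102, 104, 107, 217 excluded).
DS1_RECORDS = ("101", "106", "108", "109", "112", "114", "115", "116", "118",
               "119", "122", "124", "201", "203", "205", "207", "208", "209",
               "215", "220", "223", "230")
DS2_RECORDS = ("100", "103", "105", "111", "113", "117", "121", "123", "200",
               "202", "210", "212", "213", "214", "219", "221", "222", "228",
               "231", "232", "233", "234")


class LeakageError(RuntimeError):
    """A test record was touched before evaluation."""


def gini(p) -> float:
    """Gini impurity 1 - sum(p_i^2) of a class-probability vector."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    return float(1.0 - np.sum(p**2))


def balanced_weights(labels) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency.

    Class c gets weight N_total / (C * N_c); the weighted mass of every
    class is therefore equal and the weights sum to N_total.
    """
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("labels must be non-empty")
    classes, counts = np.unique(y, return_counts=True)
    w = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([w[c] for c in y])


def aami_group(symbols) -> np.ndarray:
    """Map MIT-BIH beat symbols to the 5 AAMI classes (N/SVEB/VEB/F/Q)."""
    out = []
    unknown = sorted({str(s) for s in symbols} - set(AAMI_MAP))
    if unknown:
        raise ValueError(f"unknown beat symbol(s): {unknown}")
    for s in symbols:
        out.append(AAMI_MAP[str(s)])
    return np.array(out)


def m_prime(m: int) -> int:
    """Per-split candidate feature count floor(sqrt(m))."""
    return int(np.floor(np.sqrt(m)))


@dataclasses.dataclass
class ForestConfig:
    n_d: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_d < 1:
            raise ValueError("n_d must be >= 1")


def train_forest(X, y, cfg: ForestConfig | None = None) -> RandomForestClassifier:
    """Fit the class-balanced forest (Gini splits, sqrt-m candidates)."""
    cfg = cfg or ForestConfig()
    model = RandomForestClassifier(
        n_estimators=cfg.n_d, criterion="gini", max_features="sqrt",
        random_state=cfg.seed, n_jobs=1)
    model.fit(np.asarray(X, dtype=float), np.asarray(y),
              sample_weight=balanced_weights(y))
    return model


@dataclasses.dataclass
class EvalReport:
    """Confusion matrix and per-class metrics under one evaluation."""

    labels: tuple
    confusion: pd.DataFrame  # rows: truth, cols: prediction
    precision: dict
    recall: dict
    f1: dict
    macro_f1: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.to_numpy().tolist(),
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "macro_f1": self.macro_f1, "accuracy": self.accuracy,
        }


def evaluate_predictions(y_true, y_pred) -> EvalReport:
    """Confusion matrix, per-class precision/recall/F1, macro-F1, accuracy.

    Precision = TP / predicted-positive, recall = TP / support, F1 their
    harmonic mean with the 0/0 -> 0 convention.  Macro-F1 is the unweighted
    mean over the classes present in the ground truth; classes that only
    appear in predictions contribute their column to the confusion matrix
    but not to the macro average.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    labels = tuple(sorted(set(y_true) | set(y_pred)))
    idx = {c: i for i, c in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    precision, recall, f1 = {}, {}, {}
    for c in labels:
        i = idx[c]
        tp = cm[i, i]
        pred_pos = cm[:, i].sum()
        support = cm[i, :].sum()
        precision[c] = tp / pred_pos if pred_pos else 0.0
        recall[c] = tp / support if support else 0.0
        pr = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / pr if pr else 0.0
    present = [c for c in labels if cm[idx[c], :].sum() > 0]
    macro = float(np.mean([f1[c] for c in present]))
    acc = float(np.trace(cm) / cm.sum())
    return EvalReport(labels, pd.DataFrame(cm, index=labels, columns=labels),
                      precision, recall, f1, macro, acc)


def evaluate(model, X_test, y_test) -> EvalReport:
    return evaluate_predictions(y_test, model.predict(np.asarray(X_test, float)))


class HeartbeatClassifier(ClassifierMixin, BaseEstimator):
    """MI-selected beat features + segment-label context -> balanced forest.

    A scikit-learn classifier over a named-column DataFrame: columns named
    in :data:`FEATURE_NAMES` undergo mutual-information ranking and the top
    ``n_features`` are kept; columns prefixed ``seg_`` (the encoded segment
    label) bypass selection and are always included.  The forest uses
    ``n_trees`` Gini trees, sqrt-m per-split candidates and balanced sample
    weights.

    Fitted attributes: ``ranking_`` (full MI ranking), ``selected_features_``,
    ``feature_columns_`` (selected + segment columns, in model order),
    ``forest_``, ``classes_``.
    """

    def __init__(self, n_features: int = 6, n_trees: int = 200,
                 seed: int = 0, mi_seed: int = 0):
        self.n_features = n_features
        self.n_trees = n_trees
        self.seed = seed
        self.mi_seed = mi_seed

    @staticmethod
    def _split_columns(X: pd.DataFrame):
        seg = [c for c in X.columns if c.startswith(SEGMENT_FEATURE_PREFIX)]
        base = [c for c in X.columns if c in FEATURE_NAMES]
        return base, seg

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named feature columns")
        y = np.asarray(y).astype(str)
        base, seg = self._split_columns(X)
        if not base:
            raise ValueError("no known beat-feature columns in X")
        self.ranking_ = mi_rank(X[base], y, seed=self.mi_seed)
        self.selected_features_ = select_top(self.ranking_, self.n_features)
        self.feature_columns_ = list(self.selected_features_) + seg
        self.forest_ = train_forest(X[self.feature_columns_], y,
                                    ForestConfig(self.n_trees, self.seed))
        self.classes_ = self.forest_.classes_
        return self

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.feature_columns_].to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._matrix(X))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._matrix(X))


def lopo_tune(record_frames: list[tuple[pd.DataFrame, np.ndarray]],
              grid, n_features: int = 6, seed: int = 0,
              mi_seed: int = 0):
    """Leave-one-patient-out tuning of the tree count.

    ``record_frames`` holds one (features, labels) pair per training record.
    For each grid value, a classifier is trained on all-but-one record and
    scored (macro-F1) on the held-out record; the value with the best mean
    score wins, ties going to the smaller tree count.

    Returns ``(best_n_d, {n_d: [per-fold macro-F1]})``.
    """
    if len(record_frames) < 2:
        raise ValueError("lopo_tune requires >= 2 training records")
    scores: dict[int, list[float]] = {}
    for n_d in grid:
        fold_scores = []
        for k in range(len(record_frames)):
            X_val, y_val = record_frames[k]
            X_tr = pd.concat([f for i, (f, _) in enumerate(record_frames)
                              if i != k], ignore_index=True)
            y_tr = np.concatenate([y for i, (_, y) in enumerate(record_frames)
                                   if i != k])
            if len(np.unique(y_tr)) < 2:
                continue
            clf = HeartbeatClassifier(n_features=n_features, n_trees=int(n_d),
                                      seed=seed, mi_seed=mi_seed).fit(X_tr, y_tr)
            fold_scores.append(
                evaluate_predictions(y_val, clf.predict(X_val)).macro_f1)
        scores[int(n_d)] = fold_scores
    best = min(scores, key=lambda n_d: (-float(np.mean(scores[n_d])), n_d))
    return best, scores
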