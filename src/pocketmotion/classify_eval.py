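"""Training and k-fold evaluation of the three activity classifiers.

Three classifier families are supported:

* ``tree`` — an entropy-criterion decision tree (scikit-learn backend) with a
  minimum leaf size, optionally post-pruned by C4.5-style error-based pruning:
  a subtree is collapsed when the pessimistic (upper-confidence-bound) error
  of the would-be leaf does not exceed the summed pessimistic errors of its
  children.  The confidence factor sets the bound's one-sided confidence
  level; smaller values prune more aggressively.
* ``naive_bayes`` — Gaussian naive Bayes written out directly: the
  class-conditional density is the product of univariate normal densities,
  one per feature, with variances floored to keep densities proper.
* ``smo_svm`` — a linear-kernel support-vector machine trained by libsvm's
  SMO solver, one-vs-one multiclass; class "probabilities" are pairwise vote
  shares (votes / number of pairs), which sum to one by construction.

Evaluation is stratified k-fold cross-validation (plain shuffled k-fold when
a class has fewer members than folds, e.g. leave-one-out); every instance is
tested exactly once and the report aggregates all test predictions into a
confusion matrix, overall accuracy, and the probability RMSE

    rmse = sqrt( mean over instances i and classes c of (p_ic - 1{c=y_i})^2 ).
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .sensor_io import ACTIVITY_LABELS, LABEL_COLUMN, ValidationError

__all__ = [
    "ClassifierSpec",
    "ConfusionMatrix",
    "EvalReport",
    "train",
    "cross_validate",
    "rmse",
    "report",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build and its hyper-parameters."""

    kind: str  # tree | naive_bayes | smo_svm
    confidence_factor: float = 0.25
    min_leaf_objects: int = 30
    pruned: bool = True
    var_floor: float = 1e-9
    kernel: str = "linear"
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "naive_bayes", "smo_svm"):
            raise ValidationError(f"unknown classifier kind {self.kind!r}")
        if not 0 < self.confidence_factor < 1:
            raise ValidationError("confidence_factor must be in (0, 1)")
        if self.min_leaf_objects < 1:
            raise ValidationError("min_leaf_objects must be >= 1")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def _c45_upper_error(errors: float, n: float, cf: float) -> float:
    """Upper confidence limit of the leaf error rate at confidence ``cf``.

    Normal approximation to the one-sided binomial upper bound used by
    C4.5's pessimistic pruning; returns a rate in [0, 1].
    """
    if n <= 0:
        return 0.0
    z = float(_norm.ppf(1.0 - cf))
    f = errors / n
    z2 = z * z
    inside = f / n - f * f / n + z2 / (4 * n * n)
    u = (f + z2 / (2 * n) + z * math.sqrt(max(inside, 0.0))) / (1 + z2 / n)
    return min(max(u, 0.0), 1.0)


class TreeModel:
    """Entropy decision tree with optional C4.5-style error-based pruning."""

    def __init__(self, spec: ClassifierSpec, random_state: int = 0):
        self.spec = spec
        self._clf = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=spec.min_leaf_objects,
            random_state=random_state,
        )
        self._pruned_nodes: set[int] = set()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TreeModel":
        self._clf.fit(X, y)
        self.classes_ = self._clf.classes_
        tree = self._clf.tree_
        # per-node class counts (tree_.value stores per-node fractions)
        self._counts = (
            tree.value[:, 0, :] * tree.weighted_n_node_samples[:, None]
        )
        self._pruned_nodes = set()
        if self.spec.pruned:
            self._prune(0)
        return self

    def _pessimistic_errors(self, node: int) -> float:
        """Predicted (pessimistic) error count of the subtree at ``node``."""
        tree = self._clf.tree_
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1 or node in self._pruned_nodes:
            c = self._counts[node]
            n = c.sum()
            errs = n - c.max()
            return n * _c45_upper_error(errs, n, self.spec.confidence_factor)
        return self._pessimistic_errors(left) + self._pessimistic_errors(right)

    def _prune(self, node: int) -> None:
        tree = self._clf.tree_
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:
            return
        self._prune(left)
        self._prune(right)
        c = self._counts[node]
        n = c.sum()
        as_leaf = n * _c45_upper_error(
            n - c.max(), n, self.spec.confidence_factor
        )
        as_subtree = self._pessimistic_errors(left) + self._pessimistic_errors(right)
        if as_leaf <= as_subtree + 1e-12:
            self._pruned_nodes.add(node)

    def _leaf_of(self, x: np.ndarray) -> int:
        tree = self._clf.tree_
        node = 0
        while tree.children_left[node] != -1 and node not in self._pruned_nodes:
            if x[tree.feature[node]] <= tree.threshold[node]:
                node = tree.children_left[node]
            else:
                node = tree.children_right[node]
        return node

    @property
    def n_leaves(self) -> int:
        """Effective leaf count after pruning."""
        tree = self._clf.tree_

        def count(node: int) -> int:
            if tree.children_left[node] == -1 or node in self._pruned_nodes:
                return 1
            return count(tree.children_left[node]) + count(tree.children_right[node])

        return count(0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = np.empty((len(X), len(self.classes_)))
        for i, x in enumerate(np.asarray(X, dtype=float)):
            c = self._counts[self._leaf_of(x)]
            out[i] = c / c.sum()
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class NaiveBayesModel:
    """Gaussian naive Bayes: product of per-feature univariate normals."""

    def __init__(self, spec: ClassifierSpec, random_state: int = 0):
        self.spec = spec

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayesModel":
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        self.theta_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = np.array(
            [np.maximum(X[y == c].var(axis=0), self.spec.var_floor)
             for c in self.classes_]
        )
        self.log_prior_ = np.log(
            np.array([(y == c).sum() for c in self.classes_]) / len(y)
        )
        return self

    def class_log_density(self, x: np.ndarray) -> np.ndarray:
        """log of the product of univariate Gaussian densities, per class."""
        x = np.asarray(x, dtype=float)
        return np.sum(
            -0.5 * np.log(2 * np.pi * self.var_)
            - 0.5 * (x - self.theta_) ** 2 / self.var_,
            axis=1,
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logp = np.array(
            [self.class_log_density(x) + self.log_prior_ for x in X]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class SmoSvmModel:
    """One-vs-one SVM (libsvm SMO solver); probabilities are vote shares."""

    def __init__(self, spec: ClassifierSpec, random_state: int = 0):
        self.spec = spec
        self._clf = SVC(
            kernel=spec.kernel,
            C=spec.C,
            decision_function_shape="ovo",
            random_state=random_state,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SmoSvmModel":
        self._clf.fit(X, y)
        self.classes_ = self._clf.classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        k = len(self.classes_)
        dec = np.atleast_2d(self._clf.decision_function(X))
        votes = np.zeros((len(dec), k))
        pair = 0
        for i in range(k):
            for j in range(i + 1, k):
                win_i = dec[:, pair] > 0
                votes[win_i, i] += 1
                votes[~win_i, j] += 1
                pair += 1
        return votes / (k * (k - 1) / 2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict(X)


_MODEL_CLASSES = {
    "tree": TreeModel,
    "naive_bayes": NaiveBayesModel,
    "smo_svm": SmoSvmModel,
}


def _split_table(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if LABEL_COLUMN not in data.columns:
        raise ValidationError(f"feature table must contain {LABEL_COLUMN!r}")
    feats = [c for c in data.columns if c != LABEL_COLUMN]
    X = data[feats].to_numpy(dtype=float)
    y = data[LABEL_COLUMN].to_numpy()
    if not np.isfinite(X).all():
        raise ValidationError("feature table contains non-finite values")
    return X, y, feats


def train(spec: ClassifierSpec, data: pd.DataFrame, seed: int = 0):
    """Fit one classifier on a feature table (features + ``label`` column)."""
    X, y, _ = _split_table(data)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain at least 2 classes")
    model = _MODEL_CLASSES[spec.kind](spec, random_state=seed)
    return model.fit(X, y)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Counts with rows = actual class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValidationError("confusion matrix must be k x k, non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.total


@dataclass
class EvalReport:
    """Aggregated cross-validation result."""

    confusion: ConfusionMatrix
    accuracy_pct: float
    rmse: float
    per_class: dict[str, dict[str, float]]
    fit_seconds: float
    k_folds: int = 0
    seed: int = 0

    def summary(self) -> str:
        return (
            f"{self.k_folds}-fold CV: accuracy {self.accuracy_pct:.1f} % "
            f"(n={self.confusion.total}), RMSE {self.rmse:.4f}, "
            f"fit {self.fit_seconds:.2f} s"
        )


def _class_order(y: np.ndarray) -> tuple[str, ...]:
    present = set(str(v) for v in np.unique(y))
    if present <= set(ACTIVITY_LABELS):
        return tuple(c for c in ACTIVITY_LABELS if c in present)
    return tuple(sorted(present))


def rmse(proba: np.ndarray, y_true_idx: np.ndarray, atol: float = 1e-6) -> float:
    """Root mean squared difference between probability rows and one-hot truth.

    Rows must sum to 1 (within ``atol``); the mean runs over instances x
    classes, so the value lies in [0, 1].
    """
    proba = np.asarray(proba, dtype=float)
    sums = proba.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValidationError("probability vectors must sum to 1")
    onehot = np.zeros_like(proba)
    onehot[np.arange(len(proba)), y_true_idx] = 1.0
    return float(np.sqrt(np.mean((proba - onehot) ** 2)))


def cross_validate(
    spec: ClassifierSpec, data: pd.DataFrame, k: int = 10, seed: int = 17
) -> EvalReport:
    """k-fold cross-validation with aggregate confusion matrix and metrics.

    Folds are stratified and shuffled under ``seed`` when every class holds
    at least ``k`` members; otherwise a plain shuffled k-fold is used (the
    leave-one-out limit cannot be stratified).  Each instance is tested
    exactly once.
    """
    X, y, _ = _split_table(data)
    n = len(y)
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} instances available")
    if k < 2:
        raise ValidationError("k must be >= 2")
    classes = _class_order(y)
    cls_index = {c: i for i, c in enumerate(classes)}
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    proba_all = np.zeros((n, len(classes)))
    pred_all = np.empty(n, dtype=object)
    tested = np.zeros(n, dtype=bool)
    fit_seconds = 0.0
    for train_idx, test_idx in splitter.split(X, y):
        model = _MODEL_CLASSES[spec.kind](spec, random_state=seed)
        t0 = time.perf_counter()
        model.fit(X[train_idx], y[train_idx])
        fit_seconds += time.perf_counter() - t0
        p = model.predict_proba(X[test_idx])
        for col, c in enumerate(model.classes_):
            proba_all[test_idx, cls_index[str(c)]] = p[:, col]
        pred_all[test_idx] = model.predict(X[test_idx])
        tested[test_idx] = True
    assert tested.all(), "every instance must be tested exactly once"

    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for yi, pi in zip(y, pred_all):
        cm[cls_index[str(yi)], cls_index[str(pi)]] += 1
    confusion = ConfusionMatrix(classes=classes, counts=cm)
    y_idx = np.array([cls_index[str(v)] for v in y])
    # renormalize defensively (a fold model missing a class leaves zero columns)
    row_sums = proba_all.sum(axis=1, keepdims=True)
    proba_all = np.where(row_sums > 0, proba_all / row_sums, proba_all)
    err = rmse(proba_all, y_idx)

    per_class = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        actual = cm[i, :].sum()
        predicted = cm[:, i].sum()
        per_class[c] = {
            "precision": tp / predicted if predicted else 0.0,
            "recall": tp / actual if actual else 0.0,
        }
    return EvalReport(
        confusion=confusion,
        accuracy_pct=confusion.accuracy_pct,
        rmse=err,
        per_class=per_class,
        fit_seconds=fit_seconds,
        k_folds=k,
        seed=seed,
    )


def report(eval_report: EvalReport, out_dir) -> tuple[Path, Path]:
    """Write ``confusion.csv`` and ``metrics.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm_path = out / "confusion.csv"
    classes = eval_report.confusion.classes
    with open(cm_path, "w") as fh:
        fh.write("actual\\predicted," + ",".join(classes) + "\n")
        for i, c in enumerate(classes):
            row = ",".join(str(v) for v in eval_report.confusion.counts[i])
            fh.write(f"{c},{row}\n")
    metrics = {
        "classes": list(classes),
        "n_instances": eval_report.confusion.total,
        "accuracy_pct": eval_report.accuracy_pct,
        "rmse": eval_report.rmse,
        "per_class": eval_report.per_class,
        "k_folds": eval_report.k_folds,
        "seed": eval_report.seed,
    }
    metrics_path = out / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return cm_path, metrics_path
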