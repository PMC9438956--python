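"""Imbalance-aware model evaluation.

Balanced accuracy (BA) — the mean of per-class recalls — is the primary
metric: it equals (TPR + TNR)/2 for binary tasks, generalises to
(1/K) * sum_c f_cc / N_c for K classes, and a classifier with no
predictive power scores 1/K regardless of class imbalance.  Confusion
matrices and per-class one-vs-rest ROC AUC complete the picture, and
repeated stratified cross-validation provides dispersion estimates for
model comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

logger = logging.getLogger(__name__)


class UndefinedClassError(ValueError):
    """A per-class metric was requested for a class with no examples."""


@dataclass
class ConfusionMatrix:
    """K×K count matrix; rows are observed classes, columns predicted."""

    classes: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        self.classes = tuple(self.classes)
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError("confusion matrix must be K x K")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def row_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.matrix, index=list(self.classes),
                     columns=list(self.classes)).to_csv(path, sep="\t")


def confusion_matrix(true_labels, predicted_labels,
                     classes) -> ConfusionMatrix:
    classes = tuple(classes)
    known = set(classes)
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in known:
            raise UndefinedClassError(f"label {lab!r} not in class list")
    m = _sk_confusion(true_labels, predicted_labels, labels=list(classes))
    return ConfusionMatrix(classes, m)


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall f_cc / N_c; classes absent from the truth raise."""
    totals = cm.row_totals()
    if (totals == 0).any():
        empty = [c for c, t in zip(cm.classes, totals) if t == 0]
        raise UndefinedClassError(
            f"classes with no observed examples: {empty}")
    return np.diag(cm.matrix) / totals


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of per-class recalls; 1/K for a no-skill classifier."""
    return float(per_class_accuracy(cm).mean())


def per_class_auc(true_labels, probability_rows, classes) -> np.ndarray:
    """One-vs-rest ROC AUC per class (Mann–Whitney rank statistic; ties
    count one half).  Classes absent from the truth get NaN."""
    true_labels = np.asarray(true_labels)
    P = np.asarray(probability_rows, dtype=float)
    out = np.full(len(classes), np.nan)
    for j, c in enumerate(classes):
        pos = true_labels == c
        if pos.all() or not pos.any():
            logger.warning("AUC undefined for class %r (one-sided truth)", c)
            continue
        out[j] = roc_auc_score(pos.astype(int), P[:, j])
    return out


@dataclass
class EvalReport:
    """Evaluation bundle: confusion, BA, per-class recalls and AUCs."""

    confusion: ConfusionMatrix
    ba: float
    per_class_accuracy: np.ndarray
    per_class_auc: np.ndarray
    n_examples: int

    def to_json(self, path=None):
        payload = {
            "classes": list(self.confusion.classes),
            "confusion": self.confusion.matrix.tolist(),
            "ba": self.ba,
            "per_class_accuracy": list(self.per_class_accuracy),
            "per_class_auc": [None if np.isnan(a) else a
                              for a in self.per_class_auc],
            "n_examples": self.n_examples,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_classifier(true_labels, probability_rows,
                        classes) -> EvalReport:
    """Score argmax predictions of a probabilistic classifier."""
    classes = tuple(classes)
    P = np.asarray(probability_rows, dtype=float)
    pred = np.asarray(classes)[P.argmax(axis=1)]
    cm = confusion_matrix(true_labels, pred, classes)
    return EvalReport(cm, balanced_accuracy(cm), per_class_accuracy(cm),
                      per_class_auc(true_labels, P, classes),
                      len(true_labels))


def binary_report_at_threshold(true_labels, p_positive, positive_class,
                               negative_class, threshold: float = 0.5):
    """Binary confusion/BA at a fixed decision threshold (default 0.5),
    the common operating point for published binary GI predictors."""
    p = np.asarray(p_positive, dtype=float)
    pred = np.where(p >= threshold, positive_class, negative_class)
    classes = (positive_class, negative_class)
    cm = confusion_matrix(true_labels, pred, classes)
    return cm, balanced_accuracy(cm)


# ---------------------------------------------------------------------------
# Splitting and cross-validation
# ---------------------------------------------------------------------------

def split_dev_test(y, test_fraction: float, seed: int,
                   stratified: bool = True):
    """Disjoint, exhaustive development/test index split.

    Stratification keeps per-class fractions within one example of the
    target; classes with a single example go to development with a
    warning (they cannot be split).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n = len(y)
    dev_idx, test_idx = [], []
    if not stratified:
        order = rng.permutation(n)
        n_test = int(round(test_fraction * n))
        return np.sort(order[n_test:]), np.sort(order[:n_test])
    for c in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == c)
        if len(idx) == 1:
            logger.warning("class %r has a single example; assigned to the "
                           "development set", c)
            dev_idx.extend(idx)
            continue
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * len(idx)))
        test_idx.extend(idx[:n_test])
        dev_idx.extend(idx[n_test:])
    return np.sort(np.array(dev_idx, dtype=int)), \
        np.sort(np.array(test_idx, dtype=int))


@dataclass
class CVPlan:
    """Repeated cross-validation layout.

    Defaults (5 folds × 10 repetitions = 50 fold evaluations) follow
    the convention of averaging over 50 replications."""

    n_folds: int = 5
    n_repetitions: int = 10
    seed: int = 0
    stratified: bool = True
    test_fraction: float = 0.2

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


def _take(X, idx):
    """Index rows of a feature container (array or (G, P) tuple)."""
    if isinstance(X, tuple):
        return tuple(np.asarray(part)[idx] for part in X)
    return np.asarray(X)[idx]


@dataclass
class CVResult:
    fold_reports: list
    repetition_bas: list[float]
    mean_ba: float
    sd_ba: float

    def to_json(self, path=None):
        payload = {"repetition_bas": self.repetition_bas,
                   "mean_ba": self.mean_ba, "sd_ba": self.sd_ba,
                   "folds": [r.to_json() for r in self.fold_reports]}
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def repeated_cv(X, y, fit_fn, plan: CVPlan | None = None,
                classes=None) -> CVResult:
    """Repeated (stratified) K-fold cross-validation.

    ``fit_fn(X_train, y_train, seed)`` must return a fitted object with
    ``predict_proba`` and ``classes``.  Each repetition reshuffles the
    folds with a repetition-specific seed derived from the plan seed.
    Returns all fold-level reports plus the per-repetition mean BAs and
    their mean ± sd.
    """
    plan = plan or CVPlan()
    y = np.asarray(y)
    n = len(y)
    if n < plan.n_folds:
        raise ValueError("fewer examples than folds")
    if classes is None:
        classes = tuple(sorted(set(y.tolist())))
    fold_reports: list[EvalReport] = []
    rep_bas: list[float] = []
    for rep in range(plan.n_repetitions):
        rep_seed = plan.seed * 10_000 + rep
        splitter_cls = StratifiedKFold if plan.stratified else KFold
        splitter = splitter_cls(n_splits=plan.n_folds, shuffle=True,
                                random_state=rep_seed % (2 ** 31))
        fold_bas = []
        for tr, te in splitter.split(np.zeros(n), y):
            model = fit_fn(_take(X, tr), y[tr], rep_seed)
            probs = np.asarray(model.predict_proba(_take(X, te)))
            order = [list(model.classes).index(c) for c in classes]
            report = evaluate_classifier(y[te], probs[:, order], classes)
            fold_reports.append(report)
            fold_bas.append(report.ba)
        rep_bas.append(float(np.mean(fold_bas)))
    return CVResult(fold_reports, rep_bas, float(np.mean(rep_bas)),
                    float(np.std(rep_bas, ddof=1)) if len(rep_bas) > 1
                    else 0.0)


def compare_models(ba_lists: dict[str, list[float]],
                   correction: int | None = None):
    """Pairwise two-sample t-tests over repetition-level BAs with a
    Bonferroni correction (C = number of pairwise comparisons by
    default).  Returns {(model_a, model_b): corrected p-value}."""
    names = list(ba_lists)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    C = correction if correction is not None else max(len(pairs), 1)
    out = {}
    for a, b in pairs:
        t, p = stats.ttest_ind(ba_lists[a], ba_lists[b], equal_var=False)
        out[(a, b)] = min(1.0, float(p) * C)
    return out
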