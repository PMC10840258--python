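"""Niche-of-origin prediction from sub-community proportions.

A multinomial logistic (softmax) classifier maps a sample's sub-community
proportion vector theta_s to its niche label, evaluated leave-one-out: the
classifier is refitted with each sample held out in turn and the held-out
prediction collected.  The proportions themselves are computed once on the
full data before the loop — matching the evaluation design this package
reproduces (the mild information leak is documented; a fully nested variant
can be built with ``lda.infer_theta``).

Metrics: overall accuracy, per-niche sensitivity, macro F1, Cohen's kappa,
multiclass Matthews correlation (Gorodkin), log loss, and the Hand-Till
pairwise-average multiclass AUC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

__all__ = [
    "PredictionReport",
    "fit_multinomial",
    "loo_evaluate",
    "metrics_from_confusion",
    "hand_till_auc",
]


@dataclass
class PredictionReport:
    """Confusion matrix (rows = reference, columns = predicted) and metrics."""

    classes: list[str]
    confusion: pd.DataFrame
    accuracy: float
    sensitivity: dict[str, float]
    macro_f1: float
    kappa: float
    mcc: float
    log_loss: float | None
    auc: float | None
    flagged_folds: list[str] = field(default_factory=list)


def fit_multinomial(
    features: np.ndarray,
    labels: np.ndarray,
    ridge: float = 1e-8,
) -> LogisticRegression:
    """Maximum-likelihood softmax regression with a tiny ridge for stability."""
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    # sklearn's penalty is (1/C) * ||w||^2 / 2 against the summed loss
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000,
                             tol=1e-8)
    clf.fit(features, labels)
    return clf


def loo_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    ridge: float = 1e-8,
    seed: int = 0,
) -> PredictionReport:
    """Leave-one-out evaluation of the niche classifier.

    ``seed`` is accepted for interface stability; the procedure is
    deterministic (convex fit, ties broken by sorted class order).  Folds
    whose training set loses a class entirely (singleton classes) are
    flagged but still evaluated.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray([str(l) for l in np.asarray(labels).ravel()])
    S = features.shape[0]
    classes = sorted(set(labels))
    m = len(classes)
    if S < m + 2:
        raise ValueError("too few samples for leave-one-out over these classes")
    class_index = {c: k for k, c in enumerate(classes)}
    probs = np.zeros((S, m))
    predicted = np.empty(S, dtype=object)
    flagged: list[str] = []
    mask = np.ones(S, dtype=bool)
    for s in range(S):
        mask[s] = False
        train_labels = labels[mask]
        if len(set(train_labels)) < len(classes):
            flagged.append(str(s))
        clf = fit_multinomial(features[mask], train_labels, ridge=ridge)
        p = clf.predict_proba(features[s][None, :])[0]
        for c, pc in zip(clf.classes_, p):
            probs[s, class_index[c]] = pc
        # argmax with ties broken by first class in sorted order
        predicted[s] = classes[int(np.argmax(probs[s]))]
        mask[s] = True
    cm = np.zeros((m, m), dtype=int)
    for true, pred in zip(labels, predicted):
        cm[class_index[true], class_index[pred]] += 1
    return metrics_from_confusion(cm, probs=probs, y_true=labels,
                                  class_names=classes, flagged_folds=flagged)


def _kappa(cm: np.ndarray) -> float:
    total = cm.sum()
    po = np.trace(cm) / total
    pe = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1))) / total**2
    return (po - pe) / (1 - pe) if pe < 1 else 1.0


def _mcc(cm: np.ndarray) -> float:
    # multiclass generalization (covariance form)
    t = cm.sum(axis=1).astype(float)   # reference marginals
    p = cm.sum(axis=0).astype(float)   # predicted marginals
    s = float(cm.sum())
    c = float(np.trace(cm))
    num = c * s - float(t @ p)
    den = np.sqrt(s**2 - float(p @ p)) * np.sqrt(s**2 - float(t @ t))
    return num / den if den > 0 else 0.0


def _macro_f1(cm: np.ndarray) -> float:
    f1s = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))


def hand_till_auc(
    y_true: np.ndarray, probs: np.ndarray, classes: list[str]
) -> float:
    """Hand-Till multiclass AUC: unweighted mean of pairwise AUCs.

    For each class pair (i, j), A(i|j) ranks the pooled i-and-j samples by
    the class-i probability (Mann-Whitney with midranks); the pair score is
    the average of A(i|j) and A(j|i).
    """
    y_true = np.asarray([str(l) for l in np.asarray(y_true).ravel()])
    idx = {c: k for k, c in enumerate(classes)}
    pair_scores = []
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            in_a = y_true == classes[a]
            in_b = y_true == classes[b]
            na, nb = int(in_a.sum()), int(in_b.sum())
            if na == 0 or nb == 0:
                continue
            pooled = in_a | in_b
            both = []
            for pos, col in ((in_a, idx[classes[a]]), (in_b, idx[classes[b]])):
                ranks = rankdata(probs[pooled, col])
                rank_sum = float(ranks[pos[pooled]].sum())
                n_pos = int(pos.sum())
                n_neg = int(pooled.sum()) - n_pos
                both.append((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
            pair_scores.append(0.5 * (both[0] + both[1]))
    return float(np.mean(pair_scores)) if pair_scores else float("nan")


def metrics_from_confusion(
    cm: np.ndarray,
    probs: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
    class_names: list[str] | None = None,
    flagged_folds: list[str] | None = None,
) -> PredictionReport:
    """Compute the evaluation metric suite from a confusion matrix.

    ``probs`` and ``y_true`` (per-sample class probabilities and reference
    labels) are needed only for log loss and AUC; classes with an empty
    reference row get ``nan`` sensitivity.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or np.any(cm < 0):
        raise ValueError("confusion matrix must be square and non-negative")
    m = cm.shape[0]
    classes = [str(c) for c in (class_names or range(m))]
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    sens = {}
    for k, c in enumerate(classes):
        row = cm[k].sum()
        sens[c] = float(cm[k, k]) / row if row > 0 else float("nan")
    ll = auc = None
    if probs is not None and y_true is not None:
        probs = np.asarray(probs, dtype=float)
        y_true = np.asarray([str(l) for l in np.asarray(y_true).ravel()])
        idx = {c: k for k, c in enumerate(classes)}
        p_true = np.clip(probs[np.arange(len(y_true)),
                               [idx[c] for c in y_true]], 1e-15, 1.0)
        ll = float(-np.mean(np.log(p_true)))
        auc = hand_till_auc(y_true, probs, classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    return PredictionReport(classes, confusion, accuracy, sens, _macro_f1(cm),
                            _kappa(cm), _mcc(cm), ll, auc,
                            list(flagged_folds or []))
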