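"""The seven-metric classification report.

Accuracy, balanced accuracy, macro precision, macro recall, macro
specificity, macro one-vs-rest AUROC, and macro F1 — macro averaging gives
each class equal weight, which matters under the heavy class imbalance of
sparse self-reported emotion data.
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics as skm

__all__ = ["METRIC_NAMES", "compute_metrics", "specificity_macro", "auroc_macro_ovr"]

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "precision_macro",
    "recall_macro",
    "specificity_macro",
    "auroc_macro",
    "f1_macro",
)


def specificity_macro(y_true, y_pred, labels) -> float:
    """Unweighted mean over classes of TN / (TN + FP), one-vs-rest."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    specs = []
    for cls in labels:
        neg = y_true != cls
        if not neg.any():
            continue
        tn = np.sum(neg & (y_pred != cls))
        specs.append(tn / neg.sum())
    return float(np.mean(specs)) if specs else float("nan")


def auroc_macro_ovr(y_true, y_score, labels) -> float:
    """Macro one-vs-rest AUROC over the given class order.

    ``y_score`` has one column per entry of ``labels`` (binary problems may
    pass a single positive-class column for ``labels[-1]``).  Classes absent
    from ``y_true``, or present in every row, contribute no term.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    labels = list(labels)
    if y_score.ndim == 1:
        if len(labels) != 2:
            raise ValueError("1-D scores require exactly 2 labels")
        y_score = np.column_stack([1.0 - y_score, y_score])
    aucs = []
    for j, cls in enumerate(labels):
        pos = y_true == cls
        if pos.all() or not pos.any():
            continue
        aucs.append(skm.roc_auc_score(pos.astype(int), y_score[:, j]))
    return float(np.mean(aucs)) if aucs else float("nan")


def compute_metrics(y_true, y_pred, y_score, labels) -> dict[str, float]:
    """Evaluate all seven metrics against the training class set ``labels``.

    Rows whose true class is absent from ``labels`` simply count as errors
    for the accuracy-type metrics and are excluded from per-class terms they
    cannot belong to.
    """
    labels = list(labels)
    out = {
        "accuracy": float(skm.accuracy_score(y_true, y_pred)),
        "balanced_accuracy": float(skm.balanced_accuracy_score(y_true, y_pred)),
        "precision_macro": float(
            skm.precision_score(y_true, y_pred, labels=labels, average="macro",
                                zero_division=0)
        ),
        "recall_macro": float(
            skm.recall_score(y_true, y_pred, labels=labels, average="macro",
                             zero_division=0)
        ),
        "specificity_macro": specificity_macro(y_true, y_pred, labels),
        "auroc_macro": auroc_macro_ovr(y_true, y_score, labels),
        "f1_macro": float(
            skm.f1_score(y_true, y_pred, labels=labels, average="macro",
                         zero_division=0)
        ),
    }
    return out
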