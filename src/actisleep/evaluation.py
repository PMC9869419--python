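"""Confusion-matrix metrics, Cohen's kappa, and sleep-efficiency results.

Conventions: confusion matrices have rows = true label, columns = predicted
label; the five-stage label order is [R, W, S1, S2, S3] (REM first). Cohen's
kappa is (p_o - p_e)/(1 - p_e) with p_e the product of matching row and
column marginals; multiclass Matthews correlation uses the covariance form.
Macro averages are unweighted over classes, with the 0-convention for empty
denominators.

Sleep efficiency (SE) is the percentage of in-bed epochs scored as sleep:

    SE (%) = total sleep time / total time in bed * 100

and the accuracy of an estimated SE against the PSG-standard SE is

    SE accuracy (%) = (1 - |standard SE - estimated SE| / standard SE) * 100.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

#: Fixed five-stage order of confusion-matrix rows/columns (REM first).
MULTICLASS_LABEL_ORDER = ("R", "W", "S1", "S2", "S3")
BINARY_LABEL_ORDER = (0, 1)  # 0 = wake, 1 = sleep

METRIC_NAMES = ("accuracy", "macro_recall", "macro_precision", "macro_f1", "kappa", "mcc")


def confusion(true_labels, pred_labels, label_order=MULTICLASS_LABEL_ORDER) -> np.ndarray:
    """K x K confusion matrix; entry (i, j) counts true=i predicted=j."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(pred_labels)} predicted"
        )
    return _sk_confusion(true_labels, pred_labels, labels=list(label_order))


def _validate_cm(cm) -> np.ndarray:
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    if cm.sum() <= 0:
        raise ValueError("confusion matrix total must be positive")
    return cm


def metrics(cm) -> dict[str, float]:
    """Accuracy, macro recall/precision/F1, Cohen's kappa and MCC of a matrix."""
    cm = _validate_cm(cm)
    n = cm.sum()
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    diag = np.diag(cm)

    accuracy = float(diag.sum() / n)

    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), 0.0)
        precision = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)

    p_o = accuracy
    p_e = float(rows @ cols) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else float("nan")

    # multiclass Matthews correlation, covariance form
    c = diag.sum()
    num = c * n - float(rows @ cols)
    den = np.sqrt((n**2 - float(cols @ cols)) * (n**2 - float(rows @ rows)))
    mcc = num / den if den > 0 else 0.0

    return {
        "accuracy": accuracy,
        "macro_recall": float(recall.mean()),
        "macro_precision": float(precision.mean()),
        "macro_f1": float(f1.mean()),
        "kappa": float(kappa),
        "mcc": float(mcc),
    }


def per_class_pr(cm, class_label, label_order=MULTICLASS_LABEL_ORDER) -> tuple[float, float]:
    """(precision, recall) for one class; 0 when a denominator is 0."""
    cm = _validate_cm(cm)
    label_order = list(label_order)
    if class_label not in label_order:
        raise ValueError(f"{class_label!r} not in label order {label_order}")
    c = label_order.index(class_label)
    colsum = cm[:, c].sum()
    rowsum = cm[c, :].sum()
    precision = float(cm[c, c] / colsum) if colsum > 0 else 0.0
    recall = float(cm[c, c] / rowsum) if rowsum > 0 else 0.0
    return precision, recall


def kappa(cm) -> float:
    """Cohen's kappa of a confusion matrix."""
    return metrics(cm)["kappa"]


def sleep_efficiency(labels, epoch_s: int = 30) -> float:
    """Sleep efficiency in % from a binary epoch sequence (1 = sleep).

    Time in bed is the full scored span, so SE reduces to the sleep-epoch
    fraction; ``epoch_s`` only fixes the (cancelling) time unit.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty epoch sequence")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0 (wake) / 1 (sleep)")
    return float(100.0 * labels.sum() / labels.size)


def se_accuracy(standard_se: float, estimated_se: float) -> float:
    """Accuracy (%) of an estimated sleep efficiency against the standard.

    Defined as (1 - |standard - estimated| / standard) * 100; the absolute
    value keeps overestimates from scoring above 100%.
    """
    if standard_se <= 0:
        raise ValueError("standard SE must be > 0")
    return float((1.0 - abs(standard_se - estimated_se) / standard_se) * 100.0)


def cohort_se_report(standard, estimated) -> dict[str, float]:
    """Cohort summary of per-subject standard vs estimated sleep efficiency.

    Returns means and (population) SDs of both lists, the mean paired
    difference, the mean per-subject SE accuracy, and the paired two-sided
    t-test statistic and p-value.
    """
    standard = np.asarray(standard, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if standard.shape != estimated.shape:
        raise ValueError("paired lists must have equal length")
    if standard.size < 2:
        raise ValueError("need >= 2 subjects")
    diff = standard - estimated
    if np.std(diff) == 0.0:
        # constant paired difference: t is 0 (no difference) or unbounded
        if diff[0] == 0.0:
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = float(np.sign(diff[0]) * np.inf), 0.0
    else:
        t_stat, p_value = stats.ttest_rel(standard, estimated)
    return {
        "standard_mean": float(standard.mean()),
        "standard_sd": float(standard.std()),
        "estimated_mean": float(estimated.mean()),
        "estimated_sd": float(estimated.std()),
        "mean_difference": float(diff.mean()),
        "mean_se_accuracy": float(
            np.mean([se_accuracy(s, e) for s, e in zip(standard, estimated)])
        ),
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
    }
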