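"""ROC/AUC, binary sensitivity–specificity, and three-way confusion reporting.

AUC is the Mann–Whitney U statistic (ties counted 1/2) divided by
``n_pos * n_neg``, which equals the trapezoidal area under the empirical ROC
curve.  Stage-level metrics condition on the true binary task (stage 2 is
evaluated on subjects whose true class is GNB or NB); end-to-end cascade
errors appear in the 3x3 confusion matrix, whose rows are predicted and
columns are true classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .selection import CLASS_LABELS

__all__ = [
    "roc_auc",
    "roc_curve_points",
    "binary_metrics",
    "three_way_report",
    "evaluate_cascade",
    "format_metrics_table",
]


def roc_auc(scores, labels) -> float:
    """AUC in [0, 1] for continuous scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) pairs at every distinct threshold, from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC undefined: both classes must be present")
    pts = [(0.0, 0.0)]
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / n1
        fpr = (pred & (labels == 0)).sum() / n0
        pts.append((float(fpr), float(tpr)))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.asarray(pts)


def binary_metrics(predictions, labels) -> dict:
    """Sensitivity, specificity, accuracy of binary predictions (1 = positive)."""
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("binary metrics need both classes present in labels")
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y),
    }


def three_way_report(predicted, true) -> dict:
    """3x3 confusion matrix (rows = predicted, columns = true) with accuracies.

    Emits both the plain overall accuracy (trace / total) and the
    macro-averaged recall (balanced accuracy).
    """
    predicted = list(predicted)
    true = list(true)
    if not true:
        raise ValueError("report requires at least one subject")
    bad = (set(predicted) | set(true)) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class label(s): {sorted(bad)}")
    idx = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    cm = np.zeros((3, 3), dtype=int)
    for p, t in zip(predicted, true):
        cm[idx[p], idx[t]] += 1
    col_tot = cm.sum(axis=0)
    per_class = {
        lab: (cm[i, i] / col_tot[i] if col_tot[i] else float("nan"))
        for i, lab in enumerate(CLASS_LABELS)
    }
    overall = float(np.trace(cm) / cm.sum())
    recalls = [v for v in per_class.values() if not np.isnan(v)]
    return {
        "confusion_matrix": cm.tolist(),
        "class_order": list(CLASS_LABELS),
        "per_class_accuracy": per_class,
        "overall_accuracy": overall,
        "balanced_accuracy": float(np.mean(recalls)),
        "n": int(cm.sum()),
    }


def evaluate_cascade(model, table: pd.DataFrame) -> dict:
    """Full evaluation of a fitted cascade on one table (train or validation).

    Returns per-stage sensitivity/specificity/accuracy/AUC (stage 2
    conditioned on true GNB/NB) plus the three-way confusion section for the
    end-to-end cascade predictions.
    """
    from .cascade import predict_cascade  # local import avoids a cycle

    preds = predict_cascade(model, table)
    true = table["label"]

    y1 = (true == "GN").to_numpy(dtype=int)
    p1 = (preds["stage1_score"] >= model.stage1.threshold).to_numpy(dtype=int)
    stage1 = binary_metrics(p1, y1)
    stage1["auc"] = roc_auc(preds["stage1_score"], y1)

    sub = true.isin(["GNB", "NB"]).to_numpy()
    y2 = (true[sub] == "GNB").to_numpy(dtype=int)
    s2 = preds.loc[sub, "stage2_score_full"].to_numpy()
    p2 = (s2 >= model.stage2.threshold).astype(int)
    stage2 = binary_metrics(p2, y2)
    stage2["auc"] = roc_auc(s2, y2)

    report = three_way_report(preds["predicted"], true)
    return {"stage1": stage1, "stage2": stage2, "three_way": report}


def format_metrics_table(report: dict) -> str:
    """Human-readable stage metrics (percentages to one decimal, AUC to three)."""
    lines = []
    for stage, task in (("stage1", "GN vs non-GN"), ("stage2", "GNB vs NB")):
        m = report[stage]
        lines.append(
            f"{task}: accuracy {m['accuracy'] * 100:.1f}%  "
            f"sensitivity {m['sensitivity'] * 100:.1f}%  "
            f"specificity {m['specificity'] * 100:.1f}%  AUC {m['auc']:.3f}"
        )
    tw = report["three_way"]
    lines.append(f"overall accuracy {tw['overall_accuracy'] * 100:.1f}%")
    return "\n".join(lines)
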