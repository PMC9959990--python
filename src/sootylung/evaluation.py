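"""Metrics, stratified splitting, k-fold cross-validation, and ROC/AUC.

Per-class metrics are one-vs-rest: precision, recall, specificity and
F-score in percent, plus the binary Matthews correlation coefficient (MCC,
in [-1, 1]) of the collapsed 2x2 table; per-class accuracy is the
one-vs-rest accuracy, overall accuracy the confusion-matrix trace over the
total.  Averages are macro (unweighted over classes).  Zero-denominator
rates are reported as 0 with a warning so reports stay total.

For ROC analysis the positive class pools ``benign`` and ``malignant``
against ``normal`` as negative (per-class curves are available by passing
explicit binary labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold


METRIC_COLUMNS = ("MCC", "Specificity", "Accuracy", "Precision", "Recall", "F-Score")


def confusion(y_true, y_pred, classes=None) -> tuple[np.ndarray, list]:
    """K x K confusion matrix (rows = true class, cols = predicted)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: k for k, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm, classes


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


@dataclass
class MetricsReport:
    """Per-class rows plus a macro-average row; rates in percent, MCC raw."""

    table: pd.DataFrame
    accuracy: float  # overall accuracy, percent

    def __str__(self) -> str:
        return (
            self.table.round(2).to_string()
            + f"\nOverall accuracy: {self.accuracy:.2f}%"
        )


def metrics(cm: np.ndarray, classes=None) -> MetricsReport:
    """One-vs-rest metrics from a confusion matrix (see module docstring)."""
    cm = np.asarray(cm, dtype=np.int64)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    if classes is None:
        classes = [f"class_{i}" for i in range(k)]
    rows = []
    for i in range(k):
        tp = float(cm[i, i])
        fn = float(cm[i].sum() - tp)
        fp = float(cm[:, i].sum() - tp)
        tn = float(total - tp - fn - fp)
        precision = 100.0 * _safe_ratio(tp, tp + fp, f"precision[{classes[i]}]")
        recall = 100.0 * _safe_ratio(tp, tp + fn, f"recall[{classes[i]}]")
        specificity = 100.0 * _safe_ratio(tn, tn + fp, f"specificity[{classes[i]}]")
        f_score = _safe_ratio(2 * precision * recall, precision + recall,
                              f"F-score[{classes[i]}]")
        mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_ratio(tp * tn - fp * fn, mcc_den, f"MCC[{classes[i]}]")
        acc_i = 100.0 * (tp + tn) / total
        rows.append({"MCC": mcc, "Specificity": specificity, "Accuracy": acc_i,
                     "Precision": precision, "Recall": recall, "F-Score": f_score})
    table = pd.DataFrame(rows, index=list(classes))
    table.loc["average"] = table.mean(axis=0)
    return MetricsReport(table=table, accuracy=100.0 * float(np.trace(cm)) / total)


def split(manifest: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0,
          stratified: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split with largest-remainder rounding.

    The train set size is ``round(train_fraction * n)`` overall; per-class
    sizes are the floors of the class quotas, with the leftover seats going
    to the classes with the largest fractional remainders.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(manifest)
    target = int(round(train_fraction * n))
    labels = manifest["label"].to_numpy() if stratified else np.zeros(n)
    classes = sorted(set(labels))
    quotas = {c: train_fraction * int(np.sum(labels == c)) for c in classes}
    take = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftovers = sorted(classes, key=lambda c: quotas[c] - take[c], reverse=True)
    for c in leftovers:
        if sum(take.values()) >= target:
            break
        take[c] += 1
    train_idx = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        train_idx.extend(rng.permutation(idx)[: take[c]])
    train_mask = np.zeros(n, dtype=bool)
    train_mask[np.asarray(train_idx, dtype=int)] = True
    return manifest.iloc[train_mask].reset_index(drop=True), \
        manifest.iloc[~train_mask].reset_index(drop=True)


def kfold(manifest: pd.DataFrame, pipeline, k: int = 5, seed: int = 0
          ) -> pd.DataFrame:
    """Stratified k-fold evaluation of a train/predict pipeline.

    ``pipeline(train_df, test_df)`` must return predicted labels for the
    test rows.  Emits one row per fold with macro-averaged Accuracy, Recall,
    Specificity and MCC, plus a ``mean`` row.
    """
    labels = manifest["label"].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels), start=1):
        train_df = manifest.iloc[tr].reset_index(drop=True)
        test_df = manifest.iloc[te].reset_index(drop=True)
        y_pred = pipeline(train_df, test_df)
        cm, classes = confusion(test_df["label"], y_pred, classes=sorted(set(labels)))
        rep = metrics(cm, classes)
        avg = rep.table.loc["average"]
        rows.append({"fold": fold, "Accuracy": rep.accuracy, "Recall": avg["Recall"],
                     "Specificity": avg["Specificity"], "MCC": avg["MCC"]})
    table = pd.DataFrame(rows).set_index("fold")
    table.loc["mean"] = table.mean(axis=0)
    return table


def pooled_positive_labels(labels) -> np.ndarray:
    """Binary polarity used for ROC: benign/malignant positive, normal negative."""
    return np.array([0 if l == "normal" else 1 for l in labels], dtype=np.int64)


def roc_auc(scores, y_binary) -> tuple[pd.DataFrame, float]:
    """Threshold-sweep ROC points and trapezoidal AUC.

    ``scores`` are higher-is-more-positive; ties are handled by the
    threshold sweep, which is equivalent to rank averaging in the AUC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_binary = np.asarray(y_binary, dtype=np.int64)
    if set(np.unique(y_binary)) - {0, 1}:
        raise ValueError("y_binary must be 0/1")
    fpr, tpr, thresholds = _sk_roc_curve(y_binary, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, float(_sk_auc(fpr, tpr))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a, b = np.asarray(a, dtype=bool), np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def convex_deficiency(mask: np.ndarray) -> float:
    """Convex-hull area minus region pixel area (boundary concavity measure)."""
    from skimage.morphology import convex_hull_image

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return float(convex_hull_image(mask).sum() - mask.sum())
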