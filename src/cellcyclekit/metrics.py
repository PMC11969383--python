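"""Classification and regression metrics shared by the SVMs and the CNNs.

AUROC and ROC curves come from scikit-learn (rank-based, ties counted 1/2,
matching the pair-counting definition); S/G2 is the positive class
everywhere in this package.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score, roc_curve


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve; raises on a single-class label set."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUROC undefined for a single-class label set")
    return float(roc_auc_score(labels, scores))


def roc_points(labels: np.ndarray, scores: np.ndarray):
    """(fpr, tpr, thresholds) swept over all score thresholds."""
    return roc_curve(labels, scores)


def accuracy_at(labels: np.ndarray, probs: np.ndarray,
                threshold: float = 0.5) -> float:
    pred = (np.asarray(probs) > threshold).astype(int)
    return float((pred == np.asarray(labels)).mean())


def confusion(labels: np.ndarray, probs: np.ndarray,
              threshold: float = 0.5) -> dict[str, int]:
    labels = np.asarray(labels).astype(int)
    pred = (np.asarray(probs) > threshold).astype(int)
    return {
        "tn": int(((pred == 0) & (labels == 0)).sum()),
        "fp": int(((pred == 1) & (labels == 0)).sum()),
        "fn": int(((pred == 0) & (labels == 1)).sum()),
        "tp": int(((pred == 1) & (labels == 1)).sum()),
    }


def regression_metrics(targets: np.ndarray, preds: np.ndarray,
                       boundary: float = 45.0) -> dict[str, float]:
    """RMSE (degrees), Pearson/Spearman r, and AUROC of the predictions
    against the boundary-binarized targets.

    Constant predictions make the correlations undefined; they are
    reported as NaN with a warning rather than raising.
    """
    import warnings

    targets = np.asarray(targets, dtype=float)
    preds = np.asarray(preds, dtype=float)
    rmse = float(np.sqrt(np.mean((preds - targets) ** 2)))
    if np.std(preds) == 0 or np.std(targets) == 0:
        warnings.warn("constant predictions or targets: correlations undefined",
                      stacklevel=2)
        pearson = spearman = float("nan")
    else:
        pearson = float(sstats.pearsonr(targets, preds).statistic)
        spearman = float(sstats.spearmanr(targets, preds).statistic)
    binary = (targets > boundary).astype(int)
    try:
        auc = auroc(binary, preds)
    except ValueError:
        auc = float("nan")
    return {"rmse": rmse, "pearson_r": pearson, "spearman_r": spearman,
            "auroc_binarized": auc}


__all__ = ["auroc", "roc_points", "accuracy_at", "confusion",
           "regression_metrics"]
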