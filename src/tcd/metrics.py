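"""Classification metric suite: accuracy, TPR/FPR, rank-statistic AUC, kappa, MAE, RMSE.

The metrics follow the conventions of classic machine-learning toolkits for
probabilistic classifiers:

* TPR — correctly classified positives over all positives; FPR analogously
  on the negatives.
* kappa — chance-corrected accuracy, (p_o − p_e) / (1 − p_e), where p_e is
  the expected agreement from the confusion-matrix marginals.
* AUC — the rank statistic P(score_pos > score_neg), counting ties as 1/2
  (equivalent to the area under the empirical ROC curve).
* MAE / RMSE — mean absolute / root-mean-square residual between the
  predicted class probability and the 0/1 label; for multiclass problems the
  residual is averaged over classes per instance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "confusion_matrix",
    "accuracy",
    "tpr",
    "fpr",
    "kappa",
    "auc_rank",
    "mae_rmse",
    "binary_metrics",
    "multiclass_metrics",
]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None):
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    k = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    return float(np.trace(cm) / cm.sum())


def tpr(cm: np.ndarray, positive: int = 1) -> float:
    """Correctly classified positive instances over all positive instances."""
    row = cm[positive]
    return float(row[positive] / row.sum()) if row.sum() else float("nan")


def fpr(cm: np.ndarray, positive: int = 1) -> float:
    """Negatives misclassified as positive over all negative instances."""
    neg = np.delete(np.arange(cm.shape[0]), positive)
    n_neg = cm[neg].sum()
    return float(cm[neg, positive].sum() / n_neg) if n_neg else float("nan")


def kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement (p_o − p_e) / (1 − p_e)."""
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=0) / n) @ (cm.sum(axis=1) / n))
    if pe == 1.0:
        return 0.0  # constant predictor on constant truth: no chance correction possible
    return float((po - pe) / (1 - pe))


def auc_rank(y_true: np.ndarray, score: np.ndarray, positive: int = 1) -> float:
    """AUC as the Mann–Whitney rank statistic on positive-class scores."""
    y_true = np.asarray(y_true)
    score = np.asarray(score, dtype=float)
    pos = score[y_true == positive]
    neg = score[y_true != positive]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (pos.size * neg.size))


def mae_rmse(y_true: np.ndarray, p_pos: np.ndarray) -> tuple[float, float]:
    """Probability residual MAE and RMSE for a binary task."""
    resid = np.abs(np.asarray(p_pos, dtype=float) - np.asarray(y_true, dtype=float))
    return float(resid.mean()), float(np.sqrt(np.mean(resid**2)))


def binary_metrics(y_true, y_pred, p_pos) -> dict[str, float]:
    cm = confusion_matrix(y_true, y_pred, n_classes=2)
    m, r = mae_rmse(y_true, p_pos)
    return {
        "accuracy": accuracy(cm),
        "tpr": tpr(cm),
        "fpr": fpr(cm),
        "auc": auc_rank(y_true, p_pos),
        "kappa": kappa(cm),
        "mae": m,
        "rmse": r,
    }


def multiclass_metrics(y_true, y_pred, proba) -> dict[str, float]:
    """Macro-averaged TPR/FPR/AUC; kappa on the full confusion matrix;
    MAE/RMSE averaged over one-hot residuals per instance."""
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    k = proba.shape[1]
    cm = confusion_matrix(y_true, y_pred, n_classes=k)
    onehot = np.eye(k)[y_true]
    resid = np.abs(proba - onehot)
    return {
        "accuracy": accuracy(cm),
        "tpr": float(np.nanmean([tpr(cm, c) for c in range(k)])),
        "fpr": float(np.nanmean([fpr(cm, c) for c in range(k)])),
        "auc": float(np.nanmean([auc_rank(y_true, proba[:, c], c) for c in range(k)])),
        "kappa": kappa(cm),
        "mae": float(resid.mean()),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }
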