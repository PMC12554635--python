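"""Evaluation metrics: accuracy and Mann-Whitney AUC."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["mann_whitney_auc", "evaluate"]


def mann_whitney_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the probability a random positive outranks a random negative.

    Computed in the Mann-Whitney form from midranks, so tied scores count
    one half.  ``y_true`` is binary with 1 = positive.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one sample of each class")
    ranks = rankdata(s)  # average ranks handle ties as 0.5
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(probs: np.ndarray, labels: list[str],
             positive_class: str = "class2",
             threshold: float = 0.5) -> tuple[float, float | None]:
    """(accuracy, AUC) from per-sample positive-class probabilities.

    Accuracy thresholds at 0.5; AUC is ``None`` when only one class is
    present in ``labels``.
    """
    p = np.asarray(probs, dtype=float)
    y = np.array([1 if lbl == positive_class else 0 for lbl in labels])
    pred = (p >= threshold).astype(int)
    accuracy = float((pred == y).mean())
    if len(set(y)) < 2:
        return accuracy, None
    return accuracy, mann_whitney_auc(y, p)
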