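"""Classification metrics used across the zoo, stacking and SHAP stages."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import f1_score


class MetricError(ValueError):
    pass


def mann_whitney_auc(y_true, scores) -> float:
    """ROC AUC via the Mann-Whitney rank statistic with 0.5 tie credit.

    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg),
    using average ranks, i.e. the probability a random positive outscores a
    random negative counting ties as half.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise MetricError("labels and scores must align")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def binary_metrics(y_true, prob, threshold: float = 0.5) -> dict[str, float]:
    """AUC, accuracy and F1 of probability scores against 0/1 labels."""
    y = np.asarray(y_true).astype(int)
    p = np.asarray(prob, dtype=float)
    pred = (p >= threshold).astype(int)
    return {
        "auc": mann_whitney_auc(y, p),
        "accuracy": float((pred == y).mean()),
        "f1": float(f1_score(y, pred, zero_division=0)),
    }
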