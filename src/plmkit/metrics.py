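"""Evaluation metrics emitted by the fine-tuning loops."""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["spearman", "auroc", "auprc"]


def spearman(y_true, y_pred) -> float:
    """Spearman rank correlation; nan-safe for constant inputs (returns 0)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return 0.0
    rho = stats.spearmanr(y_true, y_pred).statistic
    return float(rho)


def auroc(y_true, y_score) -> float:
    return float(roc_auc_score(np.asarray(y_true), np.asarray(y_score)))


def auprc(y_true, y_score) -> float:
    return float(average_precision_score(np.asarray(y_true), np.asarray(y_score)))
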