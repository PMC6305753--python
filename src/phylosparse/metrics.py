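"""Prediction, selection and estimation metrics.

PMSE is the mean squared prediction error; applied to probability predictions
of a binary outcome it is the Brier score.  R^2 is the squared Pearson
correlation between observed and predicted values (0 = no correlation,
1 = perfect), AUC the Mann-Whitney rank statistic.  Variable selection is
scored by sensitivity (proportion of truly associated OTUs selected) and
specificity (proportion of irrelevant OTUs not selected); coefficient
estimation by mean squared error over all p coefficients.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "pmse",
    "r_squared",
    "auc",
    "selection_metrics",
    "coefficient_mse",
]


def _paired(y_obs, y_pred):
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError(
            f"length mismatch: {y_obs.size} observed vs {y_pred.size} predicted"
        )
    return y_obs, y_pred


def pmse(y_obs, y_pred) -> float:
    """Mean squared difference (Brier score for probability predictions)."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    if y_obs.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((y_obs - y_pred) ** 2))


def r_squared(y_obs, y_pred) -> float:
    """Squared Pearson correlation; 0 (with a warning) if either is constant."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        warnings.warn("constant vector: R^2 defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    return float(r * r)


def auc(y_binary, scores) -> float:
    """Rank-statistic AUC; ties between case and control scores count 1/2."""
    y_binary, scores = _paired(y_binary, scores)
    if len(np.unique(y_binary)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y_binary, scores))


def selection_metrics(selected, truth, p: int) -> tuple[float, float]:
    """(sensitivity, specificity) of a selected index set against the truth."""
    selected = set(int(i) for i in selected)
    truth = set(int(i) for i in truth)
    if not truth:
        raise ValueError("truth set is empty")
    universe = set(range(p))
    if not (selected <= universe and truth <= universe):
        raise ValueError("indices outside 0..p-1")
    sens = len(selected & truth) / len(truth)
    nontruth = universe - truth
    spec = len(nontruth - selected) / len(nontruth) if nontruth else 1.0
    return float(sens), float(spec)


def coefficient_mse(beta_hat, beta_true) -> float:
    """Mean squared coefficient error over all p entries."""
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    if beta_hat.size != beta_true.size:
        raise ValueError("coefficient vectors have different lengths")
    return float(np.mean((beta_hat - beta_true) ** 2))
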