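"""Regression evaluation metrics for binding-affinity prediction.

MSE/RMSE quantify the error in pKd units; the concordance index (CI) is
the probability that a randomly drawn pair of interactions with distinct
true affinities is ranked correctly by the predictions (ties in the
predictions count 1/2; pairs tied in the true values are excluded from the
denominator); r-squared is the coefficient of determination and Spearman
the rank correlation with average ranks for ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "concordance_index", "evaluate"]


@dataclass(frozen=True)
class EvalReport:
    mse: float
    rmse: float
    ci: float
    r2: float
    spearman: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def concordance_index(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Fraction of correctly ordered pairs among pairs with distinct truths.

    Over all (i, j) with y_true_i > y_true_j, counts 1 when
    y_pred_i > y_pred_j and 1/2 when y_pred_i = y_pred_j.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    valid = dt > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("concordance index undefined: all true values tied")
    score = np.sum((dp > 0) * valid) + 0.5 * np.sum((dp == 0) * valid)
    return float(score / n_valid)


def evaluate(y_true, y_pred) -> EvalReport:
    """Full evaluation report (MSE, RMSE, CI, r2, Spearman)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D arrays of equal length")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    resid = y_pred - y_true
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r-squared undefined: constant true values")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if np.all(y_pred == y_pred[0]):
        rho = 0.0  # constant predictions carry no rank information
    else:
        rho = float(stats.spearmanr(y_true, y_pred).statistic)
    return EvalReport(mse=mse, rmse=float(np.sqrt(mse)),
                      ci=concordance_index(y_true, y_pred), r2=r2, spearman=rho)
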