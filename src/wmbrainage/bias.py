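"""Age-bias correction, brain-age gap, and performance metrics.

Brain-age regressors exhibit regression dilution: predictions of older
participants are biased young and vice versa.  The correction fits

    y_hat = alpha * y + beta

by ordinary least squares on a left-out validation set and inverts it
on new predictions,

    y_hat_co = (y_hat - beta) / alpha,

assuming (alpha, beta) generalise beyond the fit set.  The white-matter
brain-age gap is then WMBAG = y_hat_co - y.  On the fit set itself the
inversion is an algebraic identity: the OLS of y_hat_co on y has slope
1 and intercept 0, and corr(WMBAG, y) = 0 to machine precision.

Note MAE need not decrease under correction; it is reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiasModel",
    "PerformanceReport",
    "fit_bias",
    "apply_bias",
    "compute_gap",
    "performance",
    "predictions_frame",
]


@dataclass
class BiasModel:
    alpha: float
    beta: float
    n_fit: int
    fit_r2: float


@dataclass
class PerformanceReport:
    mae: float
    pearson_r: float
    spearman_gap_age: float
    n: int


def fit_bias(y, y_hat) -> BiasModel:
    """OLS of predicted on chronological age over the validation set."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points to fit the bias model")
    if np.var(y) == 0:
        raise ValueError("zero variance in chronological age; fit undefined")
    alpha, beta = np.polyfit(y, y_hat, 1)
    if abs(alpha) < 1e-6:
        raise ValueError("fitted slope ~ 0; inversion undefined")
    resid = y_hat - (alpha * y + beta)
    tot = np.sum((y_hat - y_hat.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tot if tot > 0 else np.nan
    return BiasModel(alpha=float(alpha), beta=float(beta), n_fit=int(n), fit_r2=float(r2))


def apply_bias(y_hat, model: BiasModel) -> np.ndarray:
    """Elementwise (y_hat - beta) / alpha."""
    return (np.asarray(y_hat, dtype=np.float64) - model.beta) / model.alpha


def compute_gap(y, y_hat_co) -> np.ndarray:
    """WMBAG: corrected predicted age minus chronological age."""
    y = np.asarray(y, dtype=np.float64)
    y_hat_co = np.asarray(y_hat_co, dtype=np.float64)
    if y.shape != y_hat_co.shape:
        raise ValueError("length mismatch between ages and predictions")
    return y_hat_co - y


def performance(y, predictions) -> PerformanceReport:
    """MAE, Pearson r(y, prediction), and Spearman of gap vs age."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(predictions, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("correlations need n >= 2")
    mae = float(np.mean(np.abs(p - y)))
    pearson = float(stats.pearsonr(y, p).statistic)
    gap = p - y
    # a constant gap has no rank association with age; NaN, not a warning
    if np.ptp(gap) == 0:
        spearman = float("nan")
    else:
        spearman = float(stats.spearmanr(gap, y).statistic)
    return PerformanceReport(
        mae=mae, pearson_r=pearson, spearman_gap_age=spearman, n=int(y.size)
    )


def predictions_frame(
    raw: pd.DataFrame, model: BiasModel
) -> pd.DataFrame:
    """Attach corrected age and WMBAG to a raw prediction frame.

    ``raw`` needs columns participant_id, timepoint, y, y_hat; returns a
    copy with y_hat_co and wmbag added.
    """
    out = raw.copy()
    out["y_hat_co"] = apply_bias(out["y_hat"].to_numpy(), model)
    out["wmbag"] = compute_gap(out["y"].to_numpy(), out["y_hat_co"].to_numpy())
    return out
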