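"""Evaluation indicators: R-squared, RMSE, and RMSPE.

Definitions (y the reference values, yhat the predictions, ybar the mean
of y):

    R2    = 1 - sum((y - yhat)^2) / sum((y - ybar)^2)
    RMSE  = sqrt(mean((y - yhat)^2))
    RMSPE = 100 * sqrt(mean(((y - yhat) / y)^2))      [percent]

R2 can be negative for out-of-sample predictions worse than the mean
predictor; it is only guaranteed in [0, 1] for a least-squares model
evaluated on its own calibration data. RMSPE is used per spectrum (over
its channels) to quantify autoencoder reconstruction fidelity, then
summarized min/max/mean/std across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _pair(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def r_squared(y, y_hat) -> float:
    """Coefficient of determination; may be negative for poor predictors."""
    y, y_hat = _pair(y, y_hat)
    if y.size < 2:
        raise ValueError("R2 needs at least 2 observations")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R2 undefined for a constant reference vector")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


def rmse(y, y_hat) -> float:
    """Root mean squared error, in the units of y."""
    y, y_hat = _pair(y, y_hat)
    if y.size < 1:
        raise ValueError("RMSE needs at least 1 observation")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def rmspe(y, y_hat) -> float:
    """Root mean squared percentage error (percent); y must be nonzero."""
    y, y_hat = _pair(y, y_hat)
    if np.any(y == 0):
        raise ValueError("RMSPE undefined: reference contains zeros")
    return float(100.0 * np.sqrt(np.mean(((y - y_hat) / y) ** 2)))


def rmspe_per_spectrum(Y, Y_hat) -> np.ndarray:
    """RMSPE of each row (spectrum) of Y against its reconstruction."""
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.shape != Y_hat.shape:
        raise ValueError("shape mismatch")
    return np.array([rmspe(Y[i], Y_hat[i]) for i in range(Y.shape[0])])


def rmspe_summary(Y, Y_hat) -> dict:
    """Min/max/mean/std (n-1) of per-spectrum RMSPE across samples."""
    vals = rmspe_per_spectrum(Y, Y_hat)
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
    }


def evaluate_predictions(y_cal, yhat_cal, y_pred, yhat_pred) -> dict:
    """R2/RMSE for calibration and prediction sets from the same vectors."""
    return {
        "r2_cal": r_squared(y_cal, yhat_cal),
        "rmse_cal": rmse(y_cal, yhat_cal),
        "r2_pred": r_squared(y_pred, yhat_pred),
        "rmse_pred": rmse(y_pred, yhat_pred),
    }


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Apply the table rounding convention: R2/RMSE to 4 decimals."""
    out = report.copy()
    for col in ("r2_cal", "r2_pred", "rmse_cal", "rmse_pred"):
        if col in out:
            out[col] = out[col].round(4)
    for col in out.columns:
        if col.startswith("rmspe"):
            out[col] = out[col].round(2)
    return out
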