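"""Model evaluation: R-squared, RMSE, RPD and comparison reports.

Reports mirror the usual chemometric layout: one row per
(target, model, band set) holding the number of input variables and the
calibration / cross-validation / prediction statistics plus the residual
prediction deviation RPD = SD of the predicted prediction-set values
divided by RMSEP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REPORT_COLUMNS = [
    "target", "model", "band_set", "n_variables",
    "R2_c", "RMSEC", "SD_C",
    "R2_cv", "RMSECV", "SD_CV",
    "R2_p", "RMSEP", "SD_P", "RPD",
]


def r_squared(y_pred, y_true, printed_denominator: bool = False) -> float:
    """Coefficient of determination.

    Conventional form 1 - SS_res / SS_tot with SS_tot about the mean of
    the measured values. ``printed_denominator=True`` switches the
    denominator to sum (y_pred_i - y_mean)^2, a variant occasionally seen
    in print; the conventional form is the default because it is the one
    consistent with RMSEP/SD-based diagnostics.
    """
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    if np.ptp(y_true) == 0:
        raise ValueError("measured values are constant; R2 undefined")
    ss_res = np.sum((y_pred - y_true) ** 2)
    centered = y_pred - y_true.mean() if printed_denominator else y_true - y_true.mean()
    return float(1.0 - ss_res / np.sum(centered**2))


def rmse(y_pred, y_true) -> float:
    """Root-mean-square error, in target units."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def sd(values) -> float:
    """Sample standard deviation (n - 1 denominator)."""
    return float(np.std(np.asarray(values, dtype=float), ddof=1))


def rpd(sd_pred: float, rmsep: float) -> float:
    """Residual prediction deviation: SD of the prediction set over RMSEP."""
    if rmsep <= 0:
        raise ZeroDivisionError("RMSEP must be positive for RPD")
    return float(sd_pred) / float(rmsep)


def interpret(report_row: dict) -> dict:
    """Qualitative labels for R2_p and RPD.

    R2: <=0.60 poor, 0.61-0.80 capable, 0.81-0.90 good, >0.90 excellent;
    RPD: <2.0 incapable, 2.0-2.5 usable, >2.5 good. Boundary values fall
    in the lower-valued bin (e.g. R2 = 0.80 -> capable, RPD = 2.5 ->
    usable), deterministically.
    """
    r2 = report_row["R2_p"]
    rpd_value = report_row["RPD"]
    if r2 > 0.9:
        r2_label = "excellent"
    elif r2 > 0.8:
        r2_label = "good"
    elif r2 > 0.6:
        r2_label = "capable"
    else:
        r2_label = "poor"
    if rpd_value < 2.0:
        rpd_label = "incapable"
    elif rpd_value <= 2.5:
        rpd_label = "usable"
    else:
        rpd_label = "good"
    return {"R2_p": r2_label, "RPD": rpd_label}


def evaluate_model(
    target: str,
    model_name: str,
    band_set: str,
    n_variables: int,
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_cv: np.ndarray,
    yhat_cv: np.ndarray,
    y_pred: np.ndarray,
    yhat_pred: np.ndarray,
) -> dict:
    """One report row from fitted/out-of-fold/prediction values.

    The SD columns are standard deviations of the *predicted* values of
    each set, so RPD = SD_P / RMSEP holds as an identity of the row.
    """
    rmsep = rmse(yhat_pred, y_pred)
    return {
        "target": target,
        "model": model_name,
        "band_set": band_set,
        "n_variables": n_variables,
        "R2_c": r_squared(yhat_cal, y_cal),
        "RMSEC": rmse(yhat_cal, y_cal),
        "SD_C": sd(yhat_cal),
        "R2_cv": r_squared(yhat_cv, y_cv),
        "RMSECV": rmse(yhat_cv, y_cv),
        "SD_CV": sd(yhat_cv),
        "R2_p": r_squared(yhat_pred, y_pred),
        "RMSEP": rmsep,
        "SD_P": sd(yhat_pred),
        "RPD": rpd(sd(yhat_pred), rmsep),
    }


def build_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble evaluation rows into the standard comparison table."""
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def format_report(report: pd.DataFrame) -> str:
    """Aligned-text rendering of a report table (3 decimals)."""
    with pd.option_context("display.float_format", lambda v: f"{v:.3f}"):
        return report.to_string(index=False)
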