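"""Reference-value arithmetic and the calibration/prediction split.

Reference tables are plain pandas DataFrames with columns
``slice_id, group_h, L, a, b, BI, L_over_b, WC`` (one row per slice).
The browning index (BI) and the lightness/yellowness ratio L*/b* are
derived from the measured CIELAB values; water content (WC) comes from
wet/dry weights. Model sets are formed per target by rank-based
stratification: samples are sorted by the target value and the middle
sample of every consecutive triple goes to the prediction set, giving a
2:1 calibration:prediction ratio whose prediction range is bracketed by
the calibration range.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

TARGETS = ("L", "a", "b", "BI", "L_over_b", "WC")

REFERENCE_COLUMNS = ("slice_id", "group_h", "L", "a", "b", "BI", "L_over_b", "WC")


def browning_index(L: float, a: float, b: float) -> float:
    """Browning index from CIELAB coordinates.

    BI = 100 (x - 0.31) / 0.172 with x = (a + 1.75 L) / (5.645 L + a - 3.012 b).
    Quantifies brown pigment development; higher = browner.
    """
    L = np.asarray(L, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = 5.645 * L + a - 3.012 * b
    if np.any(denom == 0):
        raise ZeroDivisionError("browning index denominator is zero")
    x = (a + 1.75 * L) / denom
    out = 100.0 * (x - 0.31) / 0.172
    return out if out.ndim else float(out)


def water_content(w_wet: float, w_dry: float) -> float:
    """Gravimetric water content (g water / g wet matter) from wet and
    oven-dry weights: WC = (w_wet - w_dry) / w_wet."""
    if w_wet <= 0:
        raise ValueError("wet weight must be positive")
    if w_dry < 0 or w_dry > w_wet:
        raise ValueError("dry weight must satisfy 0 <= w_dry <= w_wet")
    return (w_wet - w_dry) / w_wet


def average_replicates(readings: Sequence[Sequence[float]]) -> tuple:
    """Component-wise mean of replicate readings.

    For CIELAB triples, BI and L*/b* must be computed from the averaged
    L, a, b — not averaged per reading — because both are nonlinear in the
    coordinates.
    """
    if len(readings) == 0:
        raise ValueError("no readings to average")
    arr = np.asarray(readings, dtype=float)
    return tuple(arr.mean(axis=0))


def screen_outliers(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Indices of samples beyond ``k`` standard deviations from the mean.

    Transparent default screening rule applied independently per target;
    deterministic, returns sorted positional indices.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if not np.isfinite(k) or sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(x - x.mean()) > k * sd)


def split_calibration_prediction(
    values: Sequence[float], ids: Sequence | None = None
) -> np.ndarray:
    """Rank-based 2:1 calibration/prediction split.

    Sort samples by value ascending (ties broken by id for determinism);
    within each consecutive triple the middle sample joins the prediction
    set and its neighbours the calibration set. Leftover samples
    (n mod 3) go to calibration. Returns an array of labels
    ``{"calibration", "prediction"}`` aligned with the input order.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if ids is None:
        ids = np.arange(n)
    order = sorted(range(n), key=lambda i: (x[i], ids[i]))
    labels = np.full(n, "calibration", dtype=object)
    for triple_start in range(0, n - n % 3, 3):
        labels[order[triple_start + 1]] = "prediction"
    return labels


def build_reference_table(
    slice_ids: Sequence,
    group_h: Sequence,
    L: Sequence[float],
    a: Sequence[float],
    b: Sequence[float],
    WC: Sequence[float],
) -> pd.DataFrame:
    """Assemble a reference table, deriving BI and L*/b* from L, a, b."""
    L = np.asarray(L, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return pd.DataFrame(
        {
            "slice_id": list(slice_ids),
            "group_h": list(group_h),
            "L": L,
            "a": a,
            "b": b,
            "BI": browning_index(L, a, b),
            "L_over_b": L / b,
            "WC": np.asarray(WC, dtype=float),
        }
    )


def assign_sets(
    table: pd.DataFrame, target: str, outlier_k: float = 3.0
) -> pd.Series:
    """Per-target set labels: outlier screening then the rank-based split.

    Returns a Series of {"calibration", "prediction", "excluded"} aligned
    with ``table``'s index.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; choose from {TARGETS}")
    values = table[target].to_numpy(dtype=float)
    labels = pd.Series("excluded", index=table.index, dtype=object)
    excluded = screen_outliers(values, k=outlier_k)
    keep = np.setdiff1d(np.arange(len(table)), excluded)
    split = split_calibration_prediction(
        values[keep], ids=table["slice_id"].to_numpy()[keep]
    )
    labels.iloc[keep] = split
    return labels
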