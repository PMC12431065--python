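"""Evaluation surfaces: MAE, MAPE, RMSE, reliability and the four-class map.

All error metrics compare the reconstruction against actual observations at
valid dates only — missing dates have no truth to compare with, and the
observation itself is the reference. MAPE is reported in percent and is
highly sensitive to observations near zero (open water pushes it to
extremes), so dates with |y| below a small floor are excluded from it;
MAE and RMSE use all valid dates.

The four-class map cross-tabulates per-pixel MAE against reliability (the
time-mean posterior variance): class I = low error & low variance (the
model tracks the dynamics confidently), II = low error & high variance
(right on average, wide bands), III = high error & low variance
(confident systematic bias), IV = high error & high variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MAE_THRESHOLD_DEFAULT",
    "RELIABILITY_THRESHOLD_DEFAULT",
    "MAPE_FLOOR_DEFAULT",
    "pointwise_metrics",
    "metric_maps",
    "classify_cells",
    "spatial_summary",
    "holdout_mask",
]

MAE_THRESHOLD_DEFAULT = 0.012
RELIABILITY_THRESHOLD_DEFAULT = 0.000125
MAPE_FLOOR_DEFAULT = 0.01


def pointwise_metrics(
    reconstruction: np.ndarray,
    observations: np.ndarray,
    mape_floor: float = MAPE_FLOOR_DEFAULT,
) -> tuple[float, float, float]:
    """(MAE, MAPE %, RMSE) of one series pair over valid dates.

    MAE = mean |y - x|, RMSE = sqrt(mean (y - x)^2), MAPE = 100 * mean
    |y - x| / |y| over dates where |y| >= ``mape_floor``. Metrics with zero
    usable dates are NaN (undefined), never zero.
    """
    x = np.asarray(reconstruction, dtype=float)
    y = np.asarray(observations, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned")
    valid = np.isfinite(y) & np.isfinite(x)
    if not valid.any():
        return (float("nan"),) * 3
    err = y[valid] - x[valid]
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    yv = y[valid]
    usable = np.abs(yv) >= mape_floor
    mape = float(100.0 * np.mean(np.abs(err[usable] / yv[usable]))) if usable.any() else float("nan")
    return mae, mape, rmse


def metric_maps(
    reconstruction: np.ndarray,
    observations: np.ndarray,
    mape_floor: float = MAPE_FLOOR_DEFAULT,
) -> dict[str, np.ndarray]:
    """Per-pixel MAE/MAPE/RMSE grids for (time, y, x) arrays."""
    x = np.asarray(reconstruction, dtype=float)
    y = np.asarray(observations, dtype=float)
    if x.shape != y.shape:
        raise ValueError("cubes must be aligned")
    valid = np.isfinite(y) & np.isfinite(x)
    err = np.where(valid, y - x, np.nan)
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mae = np.nansum(np.abs(err), axis=0) / n
        rmse = np.sqrt(np.nansum(err**2, axis=0) / n)
        usable = valid & (np.abs(y) >= mape_floor)
        n_m = usable.sum(axis=0).astype(float)
        ape = np.where(usable, np.abs(err / y), np.nan)
        mape = 100.0 * np.nansum(ape, axis=0) / n_m
    mae[n == 0] = np.nan
    rmse[n == 0] = np.nan
    mape[n_m == 0] = np.nan
    return {"mae": mae, "mape": mape, "rmse": rmse}


def classify_cells(
    mae: np.ndarray,
    reliability: np.ndarray,
    mae_threshold: float = MAE_THRESHOLD_DEFAULT,
    reliability_threshold: float = RELIABILITY_THRESHOLD_DEFAULT,
) -> np.ndarray:
    """Four-class cross-tabulation of error against reliability.

    'Low' means strictly below the threshold; a value equal to the threshold
    counts as high. Classes: 1 = low/low, 2 = low/high, 3 = high/low,
    4 = high/high; 0 where either input is undefined.
    """
    mae = np.asarray(mae, dtype=float)
    rel = np.asarray(reliability, dtype=float)
    if mae.shape != rel.shape:
        raise ValueError("maps must be aligned")
    low_err = mae < mae_threshold
    low_rel = rel < reliability_threshold
    cls = np.zeros(mae.shape, dtype=np.int8)
    defined = np.isfinite(mae) & np.isfinite(rel)
    cls[defined & low_err & low_rel] = 1
    cls[defined & low_err & ~low_rel] = 2
    cls[defined & ~low_err & low_rel] = 3
    cls[defined & ~low_err & ~low_rel] = 4
    return cls


def spatial_summary(maps: dict[str, np.ndarray]) -> pd.DataFrame:
    """Spatial average and population SD of each metric map.

    One row per metric with columns ``avg`` and ``sd``; raises when a map
    has no defined pixel.
    """
    rows = {}
    for name, grid in maps.items():
        vals = np.asarray(grid, dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"metric map {name!r} has no defined pixels")
        rows[name] = {"avg": float(vals.mean()), "sd": float(vals.std())}
    return pd.DataFrame(rows).T[["avg", "sd"]]


def holdout_mask(
    mask: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split a validity mask for honest hold-out evaluation.

    Randomly marks ``fraction`` of the valid entries as held out; returns
    (training mask, hold-out mask). Imputation runs with the hold-out dates
    hidden and is evaluated only there.
    """
    mask = np.asarray(mask, dtype=bool)
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    held = mask & (rng.random(mask.shape) < fraction)
    return mask & ~held, held
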