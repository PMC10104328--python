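"""Intra-individual normalization and per-horse-per-trial aggregation.

Stride features are first min-max scaled to [0, 1] per horse and per
feature over the pooled pre + post strides, so the classifier sees the
pre/post contrast rather than inter-individual differences.  Each
horse-trial is then summarized by the mean and one variability metric of
every feature, giving 104 values (2 x 52) per horse per trial.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import FEATURE_NAMES

logger = logging.getLogger(__name__)

VARIABILITY_METRICS = ("RMS", "CV", "SD", "VAR")

#: default minimum strides per horse-trial for a valid aggregated vector
MIN_STRIDES = 33


def normalize_within_horse(
    stride_features: pd.DataFrame,
    feature_cols: tuple = FEATURE_NAMES,
) -> pd.DataFrame:
    """Min-max scale each feature to [0, 1] per horse over pooled trials.

    Both trials of a horse must be present so that pre and post strides
    share one scale.  A feature that is constant within a horse (max = min)
    is set to 0 for all of that horse's strides (degenerate rule).
    """
    df = stride_features.copy()
    for horse, idx in df.groupby("horse_id").groups.items():
        trials = set(df.loc[idx, "trial"])
        if not {"pre", "post"} <= trials:
            raise ValueError(f"horse {horse!r} lacks a pre or post trial")
        block = df.loc[idx, list(feature_cols)]
        lo, hi = block.min(axis=0), block.max(axis=0)
        span = hi - lo
        scaled = (block - lo) / span.replace(0.0, np.nan)
        degenerate = span.index[span == 0.0]
        # degenerate rule: constant feature -> 0 (NaN sentinels stay NaN)
        scaled[degenerate] = block[degenerate] * 0.0
        df.loc[idx, list(feature_cols)] = scaled
    return df


def variability(values: np.ndarray, metric: str) -> float:
    """One of RMS, CV, SD (sample, n-1) or VAR of a vector of values.

    CV with mean 0 is undefined and returns NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("variability needs at least two values")
    if metric == "SD":
        return float(np.std(x, ddof=1))
    if metric == "VAR":
        return float(np.var(x, ddof=1))
    if metric == "RMS":
        return float(np.sqrt(np.mean(x ** 2)))
    if metric == "CV":
        m = x.mean()
        if m == 0:
            return np.nan
        return float(np.std(x, ddof=1) / m)
    raise ValueError(f"unknown variability metric {metric!r}")


def _aggregate_block(block: pd.DataFrame, metric: str, feature_cols) -> dict:
    out: dict = {}
    for f in feature_cols:
        vals = block[f].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            out[f"mean_{f}"] = np.nan
            out[f"var_{f}"] = np.nan
            continue
        out[f"mean_{f}"] = float(vals.mean())
        out[f"var_{f}"] = variability(vals, metric)
    return out


def aggregate(
    normalized_strides: pd.DataFrame,
    metric: str = "SD",
    min_strides: int = MIN_STRIDES,
    feature_cols: tuple = FEATURE_NAMES,
    sliding_window: int | None = None,
) -> pd.DataFrame:
    """Aggregate normalized strides into 104-value horse-trial vectors.

    One row per (horse, trial): the 52 feature means followed by the 52
    variability values under ``metric``.  Horse-trials with fewer than
    ``min_strides`` strides are excluded (logged).  Strides containing a
    NaN feature are ignored for that feature's summary.

    With ``sliding_window = W`` every horse-trial instead yields one row
    per window of W consecutive strides (step 1), mirroring per-stride
    sample counts; off by default.
    """
    if metric not in VARIABILITY_METRICS:
        raise ValueError(f"unknown variability metric {metric!r}")
    rows = []
    mean_cols = [f"mean_{f}" for f in feature_cols]
    var_cols = [f"var_{f}" for f in feature_cols]
    for (horse, trial), block in normalized_strides.groupby(["horse_id", "trial"], sort=True):
        n = len(block)
        if n < min_strides:
            logger.info("aggregate: excluding %s/%s with %d < %d strides",
                        horse, trial, n, min_strides)
            continue
        if sliding_window is None:
            row = {"horse_id": horse, "trial": trial, "n_strides": n,
                   "variability_metric": metric}
            row.update(_aggregate_block(block, metric, feature_cols))
            rows.append(row)
        else:
            if sliding_window < 2 or sliding_window > n:
                raise ValueError("sliding_window must be in [2, n_strides]")
            ordered = block.sort_values("hoof_on_s") if "hoof_on_s" in block else block
            for s in range(n - sliding_window + 1):
                win = ordered.iloc[s:s + sliding_window]
                row = {"horse_id": horse, "trial": trial, "n_strides": sliding_window,
                       "variability_metric": metric, "window_index": s}
                row.update(_aggregate_block(win, metric, feature_cols))
                rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["horse_id", "trial", "n_strides",
                                     "variability_metric"] + mean_cols + var_cols)
    df = pd.DataFrame(rows)
    meta = [c for c in df.columns if c not in mean_cols + var_cols]
    return df[meta + mean_cols + var_cols]


def feature_matrix(aggregated: pd.DataFrame,
                   feature_cols: tuple = FEATURE_NAMES) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Split an aggregated table into (X, y, groups, column names).

    y is 1 for pre (the positive class) and 0 for post; groups are horse
    ids for subject-wise cross-validation.  Columns with any non-finite
    value (e.g. an undefined CV) are dropped and logged.
    """
    cols = [f"mean_{f}" for f in feature_cols] + [f"var_{f}" for f in feature_cols]
    X = aggregated[cols].to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=0)
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        logger.info("feature_matrix: dropping %d non-finite columns", len(dropped))
    cols = [c for c, k in zip(cols, keep) if k]
    X = X[:, keep]
    y = (aggregated["trial"] == "pre").to_numpy(dtype=int)
    groups = aggregated["horse_id"].to_numpy()
    return X, y, groups, cols
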