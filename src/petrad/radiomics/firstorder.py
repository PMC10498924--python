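"""First-order (intensity histogram) features of in-mask voxels."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .discretize import DiscretizationSpec, discretize

FIRST_ORDER_NAMES = (
    "mean", "median", "minimum", "maximum", "maximum_discretized", "range",
    "variance", "skewness", "kurtosis", "entropy", "energy",
    "percentile_10", "percentile_90", "interquartile_range",
    "robust_mean_absolute_deviation",
)


def first_order_features(volume: np.ndarray, mask: np.ndarray,
                         spec: DiscretizationSpec = DiscretizationSpec()) -> dict[str, float]:
    """Fixed first-order list; entropy and the discretized maximum use
    the gray levels from `spec`, everything else uses raw intensities.

    Skewness/kurtosis use the biased moment estimators (Fisher kurtosis
    excess NOT subtracted, i.e. Pearson kurtosis); constant regions give
    skewness 0 and kurtosis 0 by convention.
    """
    vals = np.asarray(volume, dtype=np.float64)[np.asarray(mask).astype(bool)]
    if vals.size == 0:
        raise ValueError("mask is empty")
    levels = discretize(volume, mask, spec)[np.asarray(mask).astype(bool)]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / vals.size
    entropy = float(-(p * np.log2(p)).sum())

    var = float(vals.var())
    if var > 0:
        skew = float(stats.skew(vals, bias=True))
        kurt = float(stats.kurtosis(vals, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    q10, q25, q75, q90 = np.percentile(vals, [10, 25, 75, 90])
    robust = vals[(vals >= q10) & (vals <= q90)]
    return {
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "minimum": float(vals.min()),
        "maximum": float(vals.max()),
        "maximum_discretized": float(levels.max()),
        "range": float(vals.max() - vals.min()),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": entropy,
        "energy": float((vals ** 2).sum()),
        "percentile_10": float(q10),
        "percentile_90": float(q90),
        "interquartile_range": float(q75 - q25),
        "robust_mean_absolute_deviation": float(np.abs(robust - robust.mean()).mean()),
    }
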