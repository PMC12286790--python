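"""First-order intensity statistics of a voxel-value sample (18 features).

Percentiles use linear interpolation between closest ranks; entropy and
uniformity discretize with a fixed bin width whose edges are anchored at
floor(min / bin_width) * bin_width.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Uniformity",
    "10Percentile",
    "90Percentile",
    "InterquartileRange",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
)


def _bin_probabilities(x: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(x.min() / bin_width) * bin_width
    idx = np.floor((x - lo) / bin_width).astype(int)
    counts = np.bincount(idx)
    return counts[counts > 0] / x.size


def firstorder_features(
    values, bin_width: float = 0.1, voxel_volume: float = 1.0
) -> dict[str, float]:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty value sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)  # non-excess kurtosis
    else:
        skew, kurt = 0.0, 0.0

    p = _bin_probabilities(x, bin_width)
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    energy = float((x**2).sum())
    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(np.ptp(x)),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": entropy,
        "Uniformity": uniformity,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(sub - sub.mean()).mean())
        if sub.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
    }
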