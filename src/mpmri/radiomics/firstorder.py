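"""First-order (intensity) and intensity-histogram features.

First-order features are computed on the raw map values inside the mask;
intensity-histogram features on the discretised levels.  Moments are
population moments (no small-sample correction); skewness and excess
kurtosis of a constant region are defined as 0; percentile interpolation is
linear between order statistics.
"""

from __future__ import annotations

import numpy as np

__all__ = ["first_order_features", "intensity_histogram_features"]


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(np.mean(x))
    d = x - mu
    m2 = float(np.mean(d**2))
    if m2 == 0:
        return mu, 0.0, 0.0, 0.0
    skew = float(np.mean(d**3) / m2**1.5)
    kurt = float(np.mean(d**4) / m2**2 - 3.0)  # excess
    return mu, m2, skew, kurt


def _dispersion(x: np.ndarray) -> dict[str, float]:
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mu = float(np.mean(x))
    mad = float(np.mean(np.abs(x - mu)))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - np.mean(robust)))) if robust.size else 0.0
    medad = float(np.mean(np.abs(x - med)))
    sd = float(np.std(x))
    cov = sd / mu if mu != 0 else 0.0
    qcd = float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0
    return {
        "Median": float(med),
        "Percentile10": float(p10),
        "Percentile25": float(p25),
        "Percentile75": float(p75),
        "Percentile90": float(p90),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": mad,
        "RobustMeanAbsoluteDeviation": rmad,
        "MedianAbsoluteDeviation": medad,
        "CoefficientOfVariation": float(cov),
        "QuartileCoefficientOfDispersion": qcd,
    }


def first_order_features(
    map3d_or_values: np.ndarray, mask: np.ndarray | None = None,
    voxel_volume: float | None = None,
) -> dict[str, float]:
    """Intensity statistics over masked (or given 1D) values."""
    if mask is not None:
        x = np.asarray(map3d_or_values, dtype=float)[np.asarray(mask, bool)]
    else:
        x = np.asarray(map3d_or_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty mask")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    mu, m2, skew, kurt = _moments(x)
    f = {
        "Mean": mu,
        "Variance": m2,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Energy": float(np.sum(x**2)),
        "RootMeanSquare": float(np.sqrt(np.mean(x**2))),
    }
    f.update(_dispersion(x))
    if voxel_volume is not None:
        f["TotalEnergy"] = float(voxel_volume * np.sum(x**2))
    return f


def intensity_histogram_features(levels_1d: np.ndarray, ng: int) -> dict[str, float]:
    """Histogram statistics over discretised levels 1..ng.

    Mode takes the lowest level on ties; histogram gradients use central
    differences with one-sided differences at the ends, and report both the
    extreme gradient and the level where it occurs (lowest level on ties).
    """
    x = np.asarray(levels_1d, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty level set")
    counts = np.bincount(x.astype(int), minlength=ng + 1)[1:].astype(float)
    p = counts / counts.sum()
    mu, m2, skew, kurt = _moments(x)
    f = {
        "Mean": mu,
        "Variance": m2,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Mode": float(int(np.argmax(counts)) + 1),
        "Entropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "Uniformity": float(np.sum(p**2)),
    }
    disp = _dispersion(x)
    for key in ("Percentile25", "Percentile75"):
        disp.pop(key)
    f.update(disp)
    if ng == 1:
        grad = np.zeros(1)
    else:
        grad = np.empty(ng)
        grad[0] = counts[1] - counts[0]
        grad[-1] = counts[-1] - counts[-2]
        if ng > 2:
            grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
    f["MaximumHistogramGradient"] = float(grad.max())
    f["MaximumHistogramGradientLevel"] = float(int(np.argmax(grad)) + 1)
    f["MinimumHistogramGradient"] = float(grad.min())
    f["MinimumHistogramGradientLevel"] = float(int(np.argmin(grad)) + 1)
    return f
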