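"""First-order (intensity histogram) features.

Moment features use population (1/n) normalization; entropy and uniformity
are computed from the discretized in-mask histogram with log base 2.
"""

from __future__ import annotations

import numpy as np

from ..grid import SegmentationMask, VolumeGrid

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES = tuple(
    f"firstorder/{n}"
    for n in (
        "mean",
        "median",
        "minimum",
        "maximum",
        "range",
        "variance",
        "skewness",
        "kurtosis",
        "p10",
        "p90",
        "interquartile_range",
        "mean_absolute_deviation",
        "rms",
        "energy",
        "entropy",
        "uniformity",
    )
)


def first_order_features(
    volume: VolumeGrid, discretized: np.ndarray, mask: SegmentationMask
) -> dict[str, float]:
    """Histogram statistics of in-mask intensities.

    ``volume`` holds the (rescaled) intensities; ``discretized`` the binned
    lattice used for entropy and uniformity. For a constant region the
    standardized moments (skewness, kurtosis) are defined as 0.
    """
    x = volume.values[mask.values]
    if x.size == 0:
        raise ValueError("mask is empty")
    mu = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    if sd > 0:
        z = (x - mu) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew, kurt = 0.0, 0.0

    levels = discretized[mask.values]
    counts = np.bincount(levels)[1:]  # level 0 is background
    p = counts[counts > 0] / levels.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    return {
        "firstorder/mean": float(mu),
        "firstorder/median": float(np.median(x)),
        "firstorder/minimum": float(x.min()),
        "firstorder/maximum": float(x.max()),
        "firstorder/range": float(x.max() - x.min()),
        "firstorder/variance": float(var),
        "firstorder/skewness": skew,
        "firstorder/kurtosis": kurt,
        "firstorder/p10": float(np.percentile(x, 10)),
        "firstorder/p90": float(np.percentile(x, 90)),
        "firstorder/interquartile_range": float(
            np.percentile(x, 75) - np.percentile(x, 25)
        ),
        "firstorder/mean_absolute_deviation": float(np.abs(x - mu).mean()),
        "firstorder/rms": float(np.sqrt(np.mean(x**2))),
        "firstorder/energy": float(np.sum(x**2)),
        "firstorder/entropy": entropy,
        "firstorder/uniformity": uniformity,
    }
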