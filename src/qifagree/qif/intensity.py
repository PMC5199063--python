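"""First-order (histogram) density statistics within the lesion mask.

Moments use population (1/n) estimators; kurtosis is reported as excess.
Skewness and excess kurtosis of a constant region are 0 by convention.
Histogram entropy uses fixed-width density bins (``bin_width_hu``) anchored
at the within-mask minimum, so it shares the gray-level resolution
convention of the co-occurrence features.
"""

from __future__ import annotations

import numpy as np

from ..volio import ImageVolume, SegmentationMask
from .params import TextureParams

__all__ = ["extract_histogram_stats", "HISTOGRAM_NAMES"]

HISTOGRAM_NAMES = (
    "Mean",
    "SD",
    "Skewness",
    "Kurtosis",
    "Histogram_Entropy",
    "P10",
    "P25",
    "P50",
    "P75",
    "P90",
)


def _binned_entropy(values: np.ndarray, bin_width: float) -> float:
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return 0.0
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] <= hi:
        edges = np.append(edges, hi + bin_width)
    counts, _ = np.histogram(values, bins=edges)
    p = counts[counts > 0] / values.size
    return float(-np.sum(p * np.log2(p)))


def extract_histogram_stats(
    volume: ImageVolume,
    mask: SegmentationMask,
    params: TextureParams = TextureParams(),
) -> dict[str, float]:
    mask.require_nonempty()
    v = volume.data[mask.data].astype(np.float64)
    mean = v.mean()
    var = v.var()  # population
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean((v - mean) ** 3) / sd**3)
        kurt = float(np.mean((v - mean) ** 4) / var**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return {
        "Mean": float(mean),
        "SD": float(sd),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Histogram_Entropy": _binned_entropy(v, params.bin_width_hu),
        "P10": float(p10),
        "P25": float(p25),
        "P50": float(p50),
        "P75": float(p75),
        "P90": float(p90),
    }
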