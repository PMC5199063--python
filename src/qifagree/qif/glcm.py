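"""Gray-level co-occurrence (GLCM) texture features in 3D.

Voxel densities are quantized into fixed-width bins (``bin_width_hu``,
capped at ``max_levels`` levels) over the within-mask range.  Co-occurrence
counts are accumulated over the 13 unique 3D direction offsets at the
configured distance (only pairs with both voxels inside the mask), summed
across directions, symmetrized and normalized to a joint probability
matrix.  Summing before normalization (rather than averaging per-direction
features) gives a single rotation-robust convention.
"""

from __future__ import annotations

import numpy as np

from ..volio import ImageVolume, SegmentationMask
from .params import TextureParams

__all__ = ["extract_glcm", "glcm_matrix", "unique_directions_3d", "GLCM_NAMES"]

GLCM_NAMES = (
    "GLCM_Energy",
    "GLCM_Entropy",
    "GLCM_Contrast",
    "GLCM_Homogeneity",
    "GLCM_Correlation",
)


def unique_directions_3d() -> list[tuple[int, int, int]]:
    """The 13 3D offsets unique up to negation (z, y, x order)."""
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0):
                    dirs.append((dz, dy, dx))
    return dirs


def _quantize(values: np.ndarray, bin_width: float, max_levels: int) -> np.ndarray:
    lo = values.min()
    lv = np.floor((values - lo) / bin_width).astype(np.int64)
    return np.minimum(lv, max_levels - 1)


def _offset_slices(offset: tuple[int, int, int], shape: tuple[int, ...]):
    src, dst = [], []
    for d, n in zip(offset, shape):
        step = d  # distance is folded into the offset by the caller
        if step >= 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm_matrix(
    volume: ImageVolume,
    mask: SegmentationMask,
    params: TextureParams = TextureParams(),
    directions: list[tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix summed over directions."""
    mask.require_nonempty()
    vals = volume.data
    m = mask.data
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[m] = _quantize(vals[m], params.bin_width_hu, params.max_levels)
    k = int(levels[m].max()) + 1
    if directions is None:
        directions = unique_directions_3d()
    d = params.glcm_distance
    counts = np.zeros((k, k), dtype=np.float64)
    for offset in directions:
        off = tuple(d * o for o in offset)
        src, dst = _offset_slices(off, vals.shape)
        valid = m[src] & m[dst]
        a = levels[src][valid]
        b = levels[dst][valid]
        counts += np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    sym = counts + counts.T
    total = sym.sum()
    if total == 0:
        # single-voxel or disconnected mask: degenerate single-cell matrix
        sym = np.zeros((k, k))
        sym[0, 0] = 1.0
        return sym
    return sym / total


def glcm_features(p: np.ndarray) -> dict[str, float]:
    k = p.shape[0]
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    nz = p > 0
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    contrast = float(np.sum(p * (i - j) ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    pi = p.sum(axis=1)
    mu_i = float(np.sum(np.arange(k) * pi))
    var_i = float(np.sum((np.arange(k) - mu_i) ** 2 * pi))
    if var_i > 0:
        corr = float(np.sum(p * (i - mu_i) * (j - mu_i)) / var_i)
    else:
        corr = 1.0  # single occupied level: perfectly concordant by convention
    return {
        "GLCM_Energy": energy,
        "GLCM_Entropy": entropy,
        "GLCM_Contrast": contrast,
        "GLCM_Homogeneity": homogeneity,
        "GLCM_Correlation": corr,
    }


def extract_glcm(
    volume: ImageVolume,
    mask: SegmentationMask,
    params: TextureParams = TextureParams(),
    directions: list[tuple[int, int, int]] | None = None,
) -> dict[str, float]:
    return glcm_features(glcm_matrix(volume, mask, params, directions))
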