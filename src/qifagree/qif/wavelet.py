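"""Multi-level 3D discrete wavelet texture features.

A separable orthogonal DWT (4-tap Daubechies, PyWavelets ``db2``, in
periodized mode so the transform is energy-preserving) is applied to the
whole volume for 2 decomposition levels.  Each of the 7 detail subbands per
level is summarized inside the mask — the mask is carried down the pyramid
by 2x2x2 max-pooling so a subband coefficient counts as "inside" if any of
the voxels it covers is — by its mean squared coefficient (energy) and the
binned entropy of coefficient magnitudes.  Level 1 is the finest scale.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..volio import ImageVolume, SegmentationMask
from .params import TextureParams, response_entropy

__all__ = ["extract_wavelet", "wavelet_subbands", "wavelet_feature_names", "DETAIL_KEYS"]

DETAIL_KEYS = ("aad", "ada", "add", "daa", "dad", "dda", "ddd")


def _halve_mask(m: np.ndarray) -> np.ndarray:
    shape = [int(np.ceil(n / 2)) for n in m.shape]
    pad = [(0, 2 * s - n) for s, n in zip(shape, m.shape)]
    mp = np.pad(m, pad, constant_values=False)
    return mp.reshape(shape[0], 2, shape[1], 2, shape[2], 2).max(axis=(1, 3, 5))


def wavelet_subbands(
    volume: ImageVolume, params: TextureParams = TextureParams()
) -> list[dict[str, np.ndarray]]:
    """Detail-subband coefficient arrays per level, finest (level 1) first."""
    coeffs = pywt.wavedecn(
        volume.data.astype(np.float64),
        params.wavelet,
        mode="periodization",
        level=params.wavelet_levels,
    )
    details = coeffs[1:]  # coarsest..finest
    return list(reversed(details))


def wavelet_feature_names(params: TextureParams = TextureParams()) -> tuple[str, ...]:
    names = []
    for level in range(1, params.wavelet_levels + 1):
        for key in DETAIL_KEYS:
            names += [
                f"Wavelet_L{level}_{key}_Energy",
                f"Wavelet_L{level}_{key}_Entropy",
            ]
    return tuple(names)


def extract_wavelet(
    volume: ImageVolume,
    mask: SegmentationMask,
    params: TextureParams = TextureParams(),
) -> dict[str, float]:
    mask.require_nonempty()
    min_side = 2**params.wavelet_levels
    if min(volume.shape) < min_side:
        raise ValueError(
            f"volume sides {volume.shape} too small for {params.wavelet_levels} "
            f"decomposition levels (need >= {min_side})"
        )
    levels = wavelet_subbands(volume, params)
    out: dict[str, float] = {}
    m = mask.data
    for level_idx, subbands in enumerate(levels, start=1):
        m = _halve_mask(m)
        for key in DETAIL_KEYS:
            c = subbands[key]
            ml = m
            # guard against off-by-one shape drift between pooling and pywt
            if ml.shape != c.shape:
                ml = ml[tuple(slice(0, s) for s in c.shape)]
            sel = c[ml]
            if sel.size == 0:
                sel = c.ravel()
            out[f"Wavelet_L{level_idx}_{key}_Energy"] = float(np.mean(sel**2))
            out[f"Wavelet_L{level_idx}_{key}_Entropy"] = response_entropy(
                np.abs(sel), params.response_entropy_bins
            )
    return out
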