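"""Laplacian-of-Gaussian (LoG) band-pass texture features.

The scale sigma is specified in mm and converted to voxels through the grid
spacing, so a given sigma selects the same physical texture coarseness at
any resolution.  Per scale, the within-mask response is summarized by its
mean, population SD and binned entropy; feature names carry the scale as an
``_s<sigma>`` suffix (e.g. ``LoG_Entropy_s2.5``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volio import ImageVolume, SegmentationMask
from .params import TextureParams, response_entropy

__all__ = ["extract_log", "log_response", "log_feature_names"]


def log_response(volume: ImageVolume, sigma_mm: float) -> np.ndarray:
    """Zero-DC Laplacian-of-Gaussian response.

    The Laplacian is taken in physical units (HU/mm^2): each axis' second
    derivative is computed in index space and divided by that axis'
    spacing squared.  The truncated discrete kernel does not sum exactly
    to zero, so the raw filter leaks a small multiple of the local mean;
    subtracting ``f * LoG(1)`` makes the effective kernel exactly zero-sum
    (a constant field maps to exactly zero).
    """
    data = volume.data.astype(np.float64)
    sig_vox = [sigma_mm / s for s in volume.spacing]

    def lap(arr: np.ndarray) -> np.ndarray:
        out = np.zeros_like(arr)
        for axis, s in enumerate(volume.spacing):
            order = [0, 0, 0]
            order[axis] = 2
            out += ndimage.gaussian_filter(arr, sig_vox, order=order, mode="nearest") / s**2
        return out

    return lap(data) - data * lap(np.ones_like(data))


def _scale_suffix(sigma: float) -> str:
    return f"s{sigma:g}"


def log_feature_names(params: TextureParams = TextureParams()) -> tuple[str, ...]:
    names = []
    for sigma in params.log_sigmas_mm:
        suf = _scale_suffix(sigma)
        names += [f"LoG_Mean_{suf}", f"LoG_SD_{suf}", f"LoG_Entropy_{suf}"]
    return tuple(names)


def extract_log(
    volume: ImageVolume,
    mask: SegmentationMask,
    params: TextureParams = TextureParams(),
) -> dict[str, float]:
    mask.require_nonempty()
    out: dict[str, float] = {}
    for sigma in params.log_sigmas_mm:
        resp = log_response(volume, sigma)[mask.data]
        suf = _scale_suffix(sigma)
        out[f"LoG_Mean_{suf}"] = float(resp.mean())
        out[f"LoG_SD_{suf}"] = float(resp.std())
        out[f"LoG_Entropy_{suf}"] = response_entropy(resp, params.response_entropy_bins)
    return out
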