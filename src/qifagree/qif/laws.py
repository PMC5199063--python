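"""Laws' texture energy features from separable 5-tap filter banks.

The five 1D kernels — Level L5, Edge E5, Spot S5, Ripple R5, Wave W5 —
combine into separable 3D filters.  The default bank is a 14-member subset
of factor multisets (every member contains at least one zero-sum factor, so
all energies are invariant to global HU offsets).  To avoid privileging an
axis, each feature averages the energy over the distinct axis-permutations
of its factor multiset.  Energy is the mean absolute filtered response
inside the mask eroded by 2 voxels (edge policy: filter support must not
straddle the lesion boundary); if erosion empties the mask the original
mask is used.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import ndimage

from ..volio import ImageVolume, SegmentationMask
from .params import TextureParams

__all__ = ["extract_laws", "laws_response", "LAWS_VECTORS", "LAWS_TRIPLES", "LAWS_NAMES"]

LAWS_VECTORS = {
    "L": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}

# factor multisets (letters sorted for naming); all contain a zero-sum factor
LAWS_TRIPLES: tuple[tuple[str, str, str], ...] = (
    ("E", "L", "L"),
    ("S", "L", "L"),
    ("R", "L", "L"),
    ("W", "L", "L"),
    ("E", "E", "L"),
    ("S", "S", "L"),
    ("R", "R", "L"),
    ("W", "W", "L"),
    ("E", "S", "L"),
    ("S", "R", "L"),
    ("E", "E", "E"),
    ("S", "S", "S"),
    ("R", "R", "R"),
    ("W", "W", "W"),
)

LAWS_NAMES = tuple(f"Laws_Energy_{a}5{b}5{c}5" for a, b, c in LAWS_TRIPLES)


def laws_response(data: np.ndarray, factors: tuple[str, str, str]) -> np.ndarray:
    """Separable correlation with the factors assigned to axes (z, y, x)."""
    out = np.asarray(data, dtype=np.float64)
    for axis, letter in enumerate(factors):
        out = ndimage.correlate1d(out, LAWS_VECTORS[letter], axis=axis, mode="nearest")
    return out


def extract_laws(
    volume: ImageVolume,
    mask: SegmentationMask,
    params: TextureParams = TextureParams(),
) -> dict[str, float]:
    mask.require_nonempty()
    core = ndimage.binary_erosion(mask.data, iterations=params.laws_erosion_voxels)
    if not core.any():
        core = mask.data
    out: dict[str, float] = {}
    for name, triple in zip(LAWS_NAMES, LAWS_TRIPLES):
        perms = sorted(set(permutations(triple)))
        energy = 0.0
        for p in perms:
            resp = laws_response(volume.data, p)
            energy += float(np.mean(np.abs(resp[core])))
        out[name] = energy / len(perms)
    return out
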