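"""Shared texture/feature extraction parameters."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TextureParams:
    """Parameters shared by the texture and boundary feature families.

    ``bin_width_hu`` controls gray-level (density) resolution for GLCM and
    histogram entropy: levels are 25-HU-wide bins over the within-mask
    range.  ``max_levels`` caps the co-occurrence matrix size.  LoG scales
    are in mm and converted to voxels through the grid spacing; feature
    names carry the scale as an ``_s<sigma>`` suffix.  The wavelet default
    is the 4-tap Daubechies filter (PyWavelets ``db2``) at 2 decomposition
    levels.
    """

    bin_width_hu: float = 25.0
    max_levels: int = 64
    glcm_distance: int = 1
    log_sigmas_mm: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    wavelet: str = "db2"
    wavelet_levels: int = 2
    response_entropy_bins: int = 64
    shape_index_bins: int = 9
    surface_smoothing_mm: float = 1.0
    profile_halfwidth_mm: float = 4.0
    profile_step_mm: float = 0.25
    max_profiles: int = 64
    sigmoid_fit_starts: int = 3
    sigmoid_min_contrast_hu: float = 10.0
    laws_erosion_voxels: int = 2

    def __post_init__(self) -> None:
        if self.bin_width_hu <= 0:
            raise ValueError("bin width must be positive")
        if len(self.log_sigmas_mm) == 0:
            raise ValueError("at least one LoG scale is required")
        if self.wavelet_levels < 1:
            raise ValueError("wavelet levels must be >= 1")


def response_entropy(values, n_bins: int) -> float:
    """Shannon entropy (bits) of equal-width-binned filter responses.

    A constant response has a single occupied bin and entropy 0.
    """
    import numpy as np

    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-np.sum(p * np.log2(p)))
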