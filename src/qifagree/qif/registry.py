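"""The feature registry and the one-call extractor.

The default registry enumerates 89 features across nine families:

====================  =====
size/shape                9
shape-index histogram     9
sigmoid sharpness         2
histogram statistics     10
GLCM                      5
Laws' energy             14
LoG                      12
wavelet                  28
====================  =====

The exact 89-entry composition is this package's documented convention,
chosen to span every family with representative, conventionally defined
members; it is frozen here and exportable as a plain-text manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ..volio import ImageVolume, SegmentationMask
from .glcm import GLCM_NAMES, extract_glcm
from .intensity import HISTOGRAM_NAMES, extract_histogram_stats
from .laws import LAWS_NAMES, extract_laws
from .logfilt import extract_log, log_feature_names
from .params import TextureParams
from .sizeshape import SIZE_SHAPE_NAMES, extract_size_shape
from .surface import (
    SIGMOID_NAMES,
    extract_shape_index,
    extract_sigmoid_slope,
    shape_index_names,
)
from .wavelet import extract_wavelet, wavelet_feature_names

__all__ = [
    "FeatureDescriptor",
    "FeatureRegistry",
    "default_registry",
    "extract_all",
    "FeatureExtractionError",
]


class FeatureExtractionError(RuntimeError):
    """Extraction failure with the offending feature/family attached."""


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str
    parameters: dict = field(default_factory=dict)


@dataclass
class FeatureRegistry:
    descriptors: list[FeatureDescriptor]

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in registry: {dupes}")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.descriptors:
            seen.setdefault(d.family, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.descriptors)

    def family_of(self, name: str) -> str:
        for d in self.descriptors:
            if d.name == name:
                return d.family
        raise KeyError(name)

    def to_manifest(self, path: str | Path) -> None:
        rows = [
            {"name": d.name, "family": d.family, "parameters": json.dumps(d.parameters)}
            for d in self.descriptors
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "FeatureRegistry":
        df = pd.read_csv(path)
        descs = [
            FeatureDescriptor(r["name"], r["family"], json.loads(r["parameters"]))
            for _, r in df.iterrows()
        ]
        return cls(descs)


def default_registry(params: TextureParams = TextureParams()) -> FeatureRegistry:
    d: list[FeatureDescriptor] = []
    for n in SIZE_SHAPE_NAMES:
        d.append(FeatureDescriptor(n, "size_shape"))
    for n in shape_index_names(params):
        d.append(
            FeatureDescriptor(n, "shape_index", {"smoothing_mm": params.surface_smoothing_mm})
        )
    for n in SIGMOID_NAMES:
        d.append(
            FeatureDescriptor(
                n,
                "sigmoid",
                {
                    "halfwidth_mm": params.profile_halfwidth_mm,
                    "step_mm": params.profile_step_mm,
                },
            )
        )
    for n in HISTOGRAM_NAMES:
        d.append(FeatureDescriptor(n, "histogram", {"bin_width_hu": params.bin_width_hu}))
    for n in GLCM_NAMES:
        d.append(
            FeatureDescriptor(
                n,
                "glcm",
                {"bin_width_hu": params.bin_width_hu, "distance": params.glcm_distance},
            )
        )
    for n in LAWS_NAMES:
        d.append(FeatureDescriptor(n, "laws", {"erosion_voxels": params.laws_erosion_voxels}))
    for n in log_feature_names(params):
        d.append(FeatureDescriptor(n, "log"))
    for n in wavelet_feature_names(params):
        d.append(
            FeatureDescriptor(
                n, "wavelet", {"wavelet": params.wavelet, "levels": params.wavelet_levels}
            )
        )
    reg = FeatureRegistry(d)
    assert len(reg) == 89, f"default registry must hold 89 features, got {len(reg)}"
    return reg


_FAMILY_EXTRACTORS: dict[str, Callable] = {
    "size_shape": lambda v, m, p: extract_size_shape(v, m),
    "shape_index": extract_shape_index,
    "sigmoid": extract_sigmoid_slope,
    "histogram": extract_histogram_stats,
    "glcm": extract_glcm,
    "laws": extract_laws,
    "log": extract_log,
    "wavelet": extract_wavelet,
}


def extract_all(
    volume: ImageVolume,
    mask: SegmentationMask,
    registry: FeatureRegistry | None = None,
    params: TextureParams = TextureParams(),
    expected_spacing_mm: float = 0.5,
) -> dict[str, float]:
    """Extract every registry feature; returns name -> finite value in registry order.

    The volume must already be isotropic at ``expected_spacing_mm``
    (resample first; extraction never resamples implicitly).
    """
    if registry is None:
        registry = default_registry(params)
    if not volume.is_isotropic(expected_spacing_mm, tol=1e-6):
        raise FeatureExtractionError(
            f"volume spacing {volume.spacing} is not isotropic at "
            f"{expected_spacing_mm} mm; resample before extraction"
        )
    if volume.shape != mask.shape:
        raise FeatureExtractionError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    mask.require_nonempty()

    values: dict[str, float] = {}
    for family in registry.families:
        fn = _FAMILY_EXTRACTORS.get(family)
        if fn is None:
            raise FeatureExtractionError(f"no extractor for family {family!r}")
        try:
            values.update(fn(volume, mask, params))
        except Exception as exc:
            raise FeatureExtractionError(f"family {family!r} failed: {exc}") from exc

    out: dict[str, float] = {}
    for name in registry.names:
        if name not in values:
            raise FeatureExtractionError(f"feature {name!r} not produced by its family")
        val = float(values[name])
        if not np.isfinite(val):
            raise FeatureExtractionError(f"feature {name!r} is non-finite: {val}")
        out[name] = val
    return out
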