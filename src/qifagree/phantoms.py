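"""Synthetic lung-lesion phantoms and a six-setting CT acquisition surrogate.

A ground-truth lesion is a lobulated ellipsoid with band-limited
Gaussian-random-field interior texture, rendered on a fine isotropic grid
(0.25 mm by default) so that every clinical slice thickness of interest
(1.25, 2.5, 5 mm) is an integer number of ground slices and partial-volume
averaging is exact slab arithmetic.

The acquisition surrogate has three stages, mirroring what reconstruction
choices do to lung CT in practice:

1. axial slab averaging over the slice thickness (partial-volume model);
2. an in-plane kernel — "Standard" (S, smooth) is a Gaussian blur; "Lung"
   (L, sharp) is the smooth result plus an unsharp-mask edge boost;
3. additive Gaussian noise, with a larger standard deviation for the sharp
   kernel (sharp reconstruction kernels amplify quantum noise).

This is deliberately not a sinogram-domain CT simulation; it reproduces the
two effects under study — slice-thickness blurring and smooth-vs-sharp
kernels — in a fully controlled, seeded way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage

from .volio import ImageVolume, SegmentationMask

__all__ = [
    "AcquisitionSetting",
    "PhantomSpec",
    "SimulationParams",
    "CohortConfig",
    "CohortItem",
    "default_settings",
    "generate_phantom",
    "simulate_setting",
    "render_mask",
    "perturb_mask",
    "generate_cohort",
    "sample_spec",
]

GROUND_SPACING_MM = 0.25  # fine grid: every default thickness is an integer slab


@dataclass(frozen=True)
class AcquisitionSetting:
    """One reconstruction setting: slice thickness (mm) + kernel letter.

    ``kernel`` is "L" (Lung, sharp) or "S" (Standard, smooth); the label is
    the thickness string plus the kernel letter, e.g. "1.25L" or "5S".
    """

    thickness_mm: float
    kernel: str

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError(f"slice thickness must be positive, got {self.thickness_mm}")
        if self.kernel not in ("L", "S"):
            raise ValueError(f"kernel must be 'L' or 'S', got {self.kernel!r}")

    @property
    def label(self) -> str:
        t = self.thickness_mm
        ts = f"{t:g}"
        return f"{ts}{self.kernel}"

    @classmethod
    def from_label(cls, label: str) -> "AcquisitionSetting":
        label = label.strip()
        if not label or label[-1] not in ("L", "S"):
            raise ValueError(f"setting label must end in 'L' or 'S': {label!r}")
        return cls(float(label[:-1]), label[-1])


def default_settings() -> list[AcquisitionSetting]:
    """The six settings: thicknesses {1.25, 2.5, 5} mm x kernels {L, S}."""
    return [
        AcquisitionSetting(t, k) for t in (1.25, 2.5, 5.0) for k in ("L", "S")
    ]


@dataclass(frozen=True)
class SimulationParams:
    """Kernel/noise surrogate parameters (all lengths in mm).

    ``sigma_smooth_mm``: in-plane Gaussian width of the Standard kernel.
    ``sigma_unsharp_mm``: width of the broader Gaussian used by the Lung
    kernel's unsharp mask.  ``unsharp_gain``: edge-boost gain alpha in
    ``L = S + alpha * (S - G_sigma_unsharp(S))``.  ``noise_factor_sharp``:
    multiplier on the noise SD for the Lung kernel (sharp reconstruction
    kernels amplify quantum noise severalfold).  The noise SD additionally
    scales as ``sqrt(noise_ref_thickness_mm / thickness)``: thinner slices
    average fewer photons, so at fixed tube current they are noisier.
    """

    sigma_smooth_mm: float = 0.8
    sigma_unsharp_mm: float = 1.5
    unsharp_gain: float = 2.0
    noise_factor_sharp: float = 3.0
    noise_ref_thickness_mm: float = 5.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion.

    The lesion surface is an ellipsoid whose radius is modulated by a smooth
    angular lobulation term; the interior carries a Gaussian random field of
    the given correlation length, scaled to ``texture_amplitude_hu`` (SD).
    ``edge_width_mm`` is the lesion's intrinsic margin diffuseness: the
    boundary indicator is blended over a Gaussian of this width (0 = sharp
    margin), emulating the spectrum from sharply circumscribed to
    ill-defined lesion boundaries.  ``noise_sd_hu`` is the base
    acquisition-noise level applied per setting.  ``center_mm`` is relative
    to the grid center; None centers the lesion.
    """

    semi_axes_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)  # (z, y, x)
    center_mm: tuple[float, float, float] | None = None
    interior_hu: float = 20.0
    texture_amplitude_hu: float = 45.0
    background_hu: float = -800.0
    lobulation_amplitude: float = 0.10
    lobulation_frequency: float = 4.0
    texture_corr_mm: float = 1.5
    edge_width_mm: float = 0.0
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_mm}")
        if self.noise_sd_hu < 0:
            raise ValueError("noise SD must be >= 0")
        if self.lobulation_amplitude < 0:
            raise ValueError("lobulation amplitude must be >= 0")


def _grid_shape(spec: PhantomSpec, spacing: float, margin_mm: float) -> tuple[int, int, int]:
    shape = []
    for a in spec.semi_axes_mm:
        half = a * (1.0 + spec.lobulation_amplitude) + margin_mm
        n = 2 * int(math.ceil(half / spacing)) + 1
        shape.append(n)
    return tuple(shape)  # type: ignore[return-value]


def generate_phantom(
    spec: PhantomSpec,
    spacing_mm: float = GROUND_SPACING_MM,
    margin_mm: float = 6.0,
    shape: tuple[int, int, int] | None = None,
) -> tuple[ImageVolume, SegmentationMask]:
    """Render the ground-truth lesion volume and its exact mask.

    Deterministic for a given (spec, spacing, shape).  Raises ``ValueError``
    if the lobulated lesion would touch or exceed the grid bounds.
    """
    if spacing_mm <= 0 or spacing_mm > 0.5:
        raise ValueError("ground-truth spacing must be in (0, 0.5] mm")
    if shape is None:
        shape = _grid_shape(spec, spacing_mm, margin_mm)
    nz, ny, nx = shape
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0]) * spacing_mm
    if spec.center_mm is not None:
        center = center + np.asarray(spec.center_mm, dtype=float)

    # bound check: maximal radius along each axis must stay inside the grid
    max_r = np.asarray(spec.semi_axes_mm) * (1.0 + spec.lobulation_amplitude)
    extent = (np.array(shape) - 1) * spacing_mm
    if np.any(center - max_r < 0) or np.any(center + max_r > extent):
        raise ValueError(
            f"lesion (max radii {max_r} mm at center {center} mm) exceeds "
            f"grid extent {extent} mm; enlarge the grid or recenter"
        )

    zz = np.arange(nz) * spacing_mm - center[0]
    yy = np.arange(ny) * spacing_mm - center[1]
    xx = np.arange(nx) * spacing_mm - center[2]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")

    az, ay, ax = spec.semi_axes_mm
    U = np.stack([Z / az, Y / ay, X / ax])
    rho = np.sqrt(np.sum(U * U, axis=0))

    rng = np.random.default_rng(spec.seed)
    if spec.lobulation_amplitude > 0:
        # smooth angular modulation of the ellipsoidal radius
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.where(rho > 0, U[0] / np.maximum(rho, 1e-12), 1.0), -1, 1))
        phi = np.arctan2(U[1], U[2])
        f = spec.lobulation_frequency
        p1, p2, p3 = rng.uniform(0, 2 * np.pi, size=3)
        g = (
            0.6 * np.sin(f * theta + p1) * np.cos(f * phi + p2)
            + 0.4 * np.cos((f - 1.0) * theta + p3) * np.sin((f + 1.0) * phi + p1)
        )
        mask = rho <= 1.0 + spec.lobulation_amplitude * g
    else:
        rng.uniform(0, 2 * np.pi, size=3)  # keep the stream position fixed
        mask = rho <= 1.0

    interior = np.full(shape, spec.interior_hu, dtype=np.float64)
    if spec.texture_amplitude_hu > 0:
        white = rng.standard_normal(shape)
        sigma_vox = spec.texture_corr_mm / spacing_mm
        grf = ndimage.gaussian_filter(white, sigma_vox, mode="reflect")
        sd = grf.std()
        if sd > 0:
            grf /= sd
        interior = interior + spec.texture_amplitude_hu * grf
    indicator = mask.astype(np.float64)
    if spec.edge_width_mm > 0:
        indicator = ndimage.gaussian_filter(
            indicator, spec.edge_width_mm / spacing_mm, mode="nearest"
        )
    data = spec.background_hu + indicator * (interior - spec.background_hu)

    sp = (spacing_mm,) * 3
    return ImageVolume(data, sp), SegmentationMask(mask, sp)


def simulate_setting(
    ground: ImageVolume,
    setting: AcquisitionSetting,
    params: SimulationParams = SimulationParams(),
    noise_sd_hu: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ImageVolume:
    """Render the ground-truth volume at one acquisition setting.

    Axial slab average over the slice thickness, then the in-plane kernel,
    then additive Gaussian noise (SD multiplied by ``noise_factor_sharp``
    for the Lung kernel).  The output carries the setting's slice spacing.
    """
    dz = ground.spacing[0]
    ratio = setting.thickness_mm / dz
    m = int(round(ratio))
    if m < 1 or setting.thickness_mm < dz - 1e-9:
        raise ValueError(
            f"slice thickness {setting.thickness_mm} mm is smaller than the "
            f"ground-truth axial spacing {dz} mm"
        )
    if abs(ratio - m) > 1e-6:
        raise ValueError(
            f"ground-truth axial spacing {dz} mm does not divide the slice "
            f"thickness {setting.thickness_mm} mm"
        )
    nz = ground.shape[0]
    n_slabs = nz // m
    if n_slabs < 1:
        raise ValueError("volume thinner than one slab")
    # center-crop so dropped slices are split between the two z faces
    start = (nz - n_slabs * m) // 2
    sub = ground.data[start : start + n_slabs * m]
    slabbed = sub.reshape(n_slabs, m, *ground.shape[1:]).mean(axis=1)

    sig_vox = params.sigma_smooth_mm / np.asarray(ground.spacing[1:])
    smooth = ndimage.gaussian_filter(slabbed, (0.0, *sig_vox), mode="nearest")
    thickness_gain = float(np.sqrt(params.noise_ref_thickness_mm / setting.thickness_mm))
    if setting.kernel == "S":
        out = smooth
        sd = noise_sd_hu * thickness_gain
    else:
        sig_u = params.sigma_unsharp_mm / np.asarray(ground.spacing[1:])
        broad = ndimage.gaussian_filter(smooth, (0.0, *sig_u), mode="nearest")
        out = smooth + params.unsharp_gain * (smooth - broad)
        sd = noise_sd_hu * params.noise_factor_sharp * thickness_gain

    if sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        out = out + rng.normal(0.0, sd, size=out.shape)

    # slab centers sit at origin_z + start*dz + (m-1)/2*dz
    oz = ground.origin[0] + (start + (m - 1) / 2.0) * dz
    return ImageVolume(
        out,
        (setting.thickness_mm, ground.spacing[1], ground.spacing[2]),
        (oz, ground.origin[1], ground.origin[2]),
    )


def render_mask(mask: SegmentationMask, setting: AcquisitionSetting) -> SegmentationMask:
    """Render the ground-truth mask on the setting's slice grid.

    Slab-averages the binary field over the slice thickness and thresholds
    at 0.5 (majority occupancy), i.e. the partial-volume model applied to
    the lesion indicator with no kernel and no noise.
    """
    vol = ImageVolume(mask.data.astype(np.float64), mask.spacing, mask.origin)
    setting_nokernel = AcquisitionSetting(setting.thickness_mm, "S")
    params = SimulationParams(sigma_smooth_mm=0.0)
    out = simulate_setting(vol, setting_nokernel, params=params, noise_sd_hu=0.0)
    return SegmentationMask(out.data >= 0.5, out.spacing, out.origin)


def perturb_mask(
    mask: SegmentationMask,
    seed: int,
    magnitude_mm: float = 0.75,
    corr_mm: float = 5.0,
) -> SegmentationMask:
    """Produce a plausible independent-rater variant of a mask.

    Shifts the boundary by a smooth, zero-mean random field applied to the
    signed Euclidean distance (positive outside), so the perturbation is
    boundary-localized and the interior core is preserved.  Magnitude 0 is
    the identity.
    """
    mask.require_nonempty()
    arr = mask.data
    sampling = mask.spacing
    signed = ndimage.distance_transform_edt(~arr, sampling=sampling) - \
        ndimage.distance_transform_edt(arr, sampling=sampling)
    if magnitude_mm == 0:
        return SegmentationMask(signed < 0, mask.spacing, mask.origin)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(arr.shape)
    sig_vox = corr_mm / np.asarray(sampling)
    fld = ndimage.gaussian_filter(white, sig_vox, mode="reflect")
    sd = fld.std()
    if sd > 0:
        fld /= sd
    out = signed < magnitude_mm * fld
    if not out.any():
        raise ValueError("perturbation erased the mask; reduce magnitude")
    return SegmentationMask(out, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Sampling ranges for a simulated lesion cohort.

    Semi-axes are drawn per axis from ``semi_axis_range_mm``, giving lesion
    volumes of roughly 9e2 to 1.4e4 mm^3 — compact solid lung lesions at
    the lower end of the clinically reported size span, kept modest so a
    full cohort renders and extracts at desk scale.  Texture amplitude and
    correlation length vary widely across lesions (real tumors range from
    near-homogeneous to strongly heterogeneous), which is what gives the
    cohort its between-tumor feature variance.  ``noise_sd_range_hu`` is
    the Standard-kernel noise level at the 5 mm reference thickness.
    """

    semi_axis_range_mm: tuple[float, float] = (6.0, 15.0)
    interior_hu_range: tuple[float, float] = (-500.0, 60.0)
    texture_amplitude_range_hu: tuple[float, float] = (20.0, 80.0)
    lobulation_amplitude_range: tuple[float, float] = (0.05, 0.14)
    lobulation_frequency_choices: tuple[float, ...] = (3.0, 4.0, 5.0)
    texture_corr_range_mm: tuple[float, float] = (1.0, 3.0)
    edge_width_range_mm: tuple[float, float] = (0.3, 2.0)
    noise_sd_range_hu: tuple[float, float] = (6.0, 14.0)
    background_hu: float = -800.0


@dataclass(frozen=True)
class CohortItem:
    tumor_id: str
    setting: AcquisitionSetting
    volume: ImageVolume
    mask: SegmentationMask


def sample_spec(rng: np.random.Generator, config: CohortConfig = CohortConfig()) -> PhantomSpec:
    u = rng.uniform
    return PhantomSpec(
        semi_axes_mm=tuple(u(*config.semi_axis_range_mm, size=3)),
        interior_hu=float(u(*config.interior_hu_range)),
        texture_amplitude_hu=float(u(*config.texture_amplitude_range_hu)),
        background_hu=config.background_hu,
        lobulation_amplitude=float(u(*config.lobulation_amplitude_range)),
        lobulation_frequency=float(rng.choice(config.lobulation_frequency_choices)),
        texture_corr_mm=float(u(*config.texture_corr_range_mm)),
        edge_width_mm=float(u(*config.edge_width_range_mm)),
        noise_sd_hu=float(u(*config.noise_sd_range_hu)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_lesions: int,
    settings: Sequence[AcquisitionSetting] | None = None,
    seed: int = 0,
    config: CohortConfig = CohortConfig(),
    params: SimulationParams = SimulationParams(),
) -> Iterator[CohortItem]:
    """Yield ``n_lesions x len(settings)`` rendered volume/mask pairs.

    One shared ground truth per lesion, rendered at every setting with
    independent per-setting noise.  All randomness flows from ``seed``
    through per-lesion derived seeds, so two cohorts with the same seed are
    identical.  Items are yielded lazily (a full cohort does not fit
    comfortably in memory at once).
    """
    if n_lesions < 2:
        raise ValueError("a cohort needs at least 2 lesions")
    if settings is None:
        settings = default_settings()
    if len(settings) == 0:
        raise ValueError("at least one acquisition setting is required")
    master = np.random.default_rng(seed)
    for i in range(n_lesions):
        lesion_seed = int(master.integers(0, 2**31 - 1))
        lesion_rng = np.random.default_rng(lesion_seed)
        spec = sample_spec(lesion_rng, config)
        ground, gmask = generate_phantom(spec)
        tumor_id = f"T{i + 1:02d}"
        for setting in settings:
            noise_rng = np.random.default_rng(int(lesion_rng.integers(0, 2**31 - 1)))
            vol = simulate_setting(
                ground, setting, params=params, noise_sd_hu=spec.noise_sd_hu, rng=noise_rng
            )
            msk = render_mask(gmask, setting)
            yield CohortItem(tumor_id, setting, vol, msk)
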