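"""Volumes, masks and feature tables: in-memory containers and disk I/O.

Axis convention (used everywhere in this package): arrays are indexed
``(z, y, x)`` and ``spacing`` / ``origin`` are stored in the same ``(z, y, x)``
order, in millimetres.  SimpleITK stores geometry as ``(x, y, z)``; the
readers/writers below do the flip once so nothing else has to.

The :class:`FeatureTable` is the pipeline's central exchange object: one
finite value per ``(tumor, setting, feature)`` key, with every
``(tumor, setting)`` observation carrying the identical feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "FeatureTable",
    "VolumeIOError",
    "FeatureTableError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
    "ingest_s1",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class VolumeIOError(ValueError):
    """Raised for unreadable, unsupported or geometrically invalid volumes."""


class FeatureTableError(ValueError):
    """Raised when a feature table violates its key/completeness contract."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid of densities (HU) with anisotropic voxel spacing.

    ``data`` is indexed (z, y, x); ``spacing`` and ``origin`` follow the same
    axis order, in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeIOError(f"volume must be 3D, got ndim={arr.ndim}")
        if arr.size == 0:
            raise VolumeIOError("volume grid is empty")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(arr)):
            raise VolumeIOError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_isotropic(self, spacing: float, *, tol: float = 1e-6) -> bool:
        return all(abs(s - spacing) <= tol for s in self.spacing)


@dataclass(frozen=True)
class SegmentationMask:
    """Binary grid aligned voxel-for-voxel with an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeIOError(f"mask must be 3D, got ndim={arr.ndim}")
        if arr.size == 0:
            raise VolumeIOError("mask grid is empty")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise VolumeIOError("mask values must be binary (0/1)")
            object.__setattr__(self, "data", arr.astype(bool))
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_foreground * self.voxel_volume_mm3

    def require_nonempty(self) -> None:
        if self.n_foreground == 0:
            raise VolumeIOError("mask has no foreground voxels")


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeIOError(
            f"unsupported volume format {path.suffix!r}; use one of {_SUPPORTED_SUFFIXES}"
        )
    return path


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise VolumeIOError(f"expected a 3D payload, got ndim={arr.ndim}")
    sp_xyz = img.GetSpacing()
    or_xyz = img.GetOrigin()
    spacing = (float(sp_xyz[2]), float(sp_xyz[1]), float(sp_xyz[0]))
    origin = (float(or_xyz[2]), float(or_xyz[1]), float(or_xyz[0]))
    return arr, spacing, origin


def _to_sitk(data: np.ndarray, spacing: Sequence[float], origin: Sequence[float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing((float(spacing[2]), float(spacing[1]), float(spacing[0])))
    img.SetOrigin((float(origin[2]), float(origin[1]), float(origin[0])))
    return img


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI or MetaImage file into an :class:`ImageVolume`."""
    path = _check_path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # corrupt header etc.
        raise VolumeIOError(f"failed to read {path}: {exc}") from exc
    arr, spacing, origin = _from_sitk(img)
    return ImageVolume(arr.astype(np.float64), spacing, origin)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    path = _check_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(volume.data, volume.spacing, volume.origin), str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    """Read a binary mask; any nonzero voxel is foreground."""
    vol = read_volume(path)
    return SegmentationMask(vol.data > 0.5, vol.spacing, vol.origin)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    path = _check_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(
        _to_sitk(mask.data.astype(np.uint8), mask.spacing, mask.origin), str(path)
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("tumor", "setting", "feature", "value")


@dataclass
class FeatureTable:
    """Values indexed by (tumor, setting, feature).

    Internally a long-layout DataFrame with columns
    ``tumor, setting, feature, value``; validated on construction:
    no duplicate keys, a rectangular feature set and finite values.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FeatureTableError(f"missing columns: {missing}")
        df = df.loc[:, list(LONG_COLUMNS)].copy()
        df["tumor"] = df["tumor"].astype(str)
        df["setting"] = df["setting"].astype(str)
        df["feature"] = df["feature"].astype(str)
        try:
            df["value"] = pd.to_numeric(df["value"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FeatureTableError(f"non-numeric feature value: {exc}") from exc
        if df["value"].isna().any() or not np.all(np.isfinite(df["value"].to_numpy())):
            bad = df.loc[~np.isfinite(df["value"].to_numpy(dtype=float)), ["tumor", "setting", "feature"]]
            raise FeatureTableError(
                f"non-finite values at keys: {bad.head(5).to_dict('records')}"
            )
        dup = df.duplicated(subset=["tumor", "setting", "feature"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["tumor", "setting", "feature"]].tolist()
            raise FeatureTableError(f"duplicate (tumor, setting, feature) key: {key}")
        # rectangularity: every (tumor, setting) row carries the same feature set
        counts = df.groupby(["tumor", "setting"], sort=False)["feature"].agg(frozenset)
        if counts.nunique() > 1:
            sets = counts.unique()
            diff = set(sets[0]) ^ set(sets[1])
            raise FeatureTableError(
                f"ragged feature sets across (tumor, setting) rows; e.g. differing in {sorted(diff)[:5]}"
            )
        self.df = df.sort_values(["tumor", "setting", "feature"], kind="stable").reset_index(
            drop=True
        )

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, float]]
    ) -> "FeatureTable":
        return cls(pd.DataFrame(records, columns=list(LONG_COLUMNS)))

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "FeatureTable":
        """Build from a wide frame: one row per tumor x setting, one column per feature.

        The wide frame must carry ``tumor`` and ``setting`` columns.
        """
        if "tumor" not in wide.columns or "setting" not in wide.columns:
            raise FeatureTableError("wide layout requires 'tumor' and 'setting' columns")
        long = wide.melt(id_vars=["tumor", "setting"], var_name="feature", value_name="value")
        return cls(long)

    # -- accessors ----------------------------------------------------------
    @property
    def tumors(self) -> list[str]:
        return sorted(self.df["tumor"].unique())

    @property
    def settings(self) -> list[str]:
        return sorted(self.df["setting"].unique())

    @property
    def features(self) -> list[str]:
        return sorted(self.df["feature"].unique())

    def to_wide(self) -> pd.DataFrame:
        """One row per (tumor, setting), one column per feature."""
        wide = self.df.pivot_table(
            index=["tumor", "setting"], columns="feature", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        return wide

    def feature_profiles(self) -> pd.DataFrame:
        """Features as columns, one row per (tumor, setting) observation.

        This is the profile matrix clustering operates on: each feature's
        profile is its value vector over all tumor x setting observations.
        """
        wide = self.to_wide()
        return wide.set_index(["tumor", "setting"]).sort_index()

    def values_at(self, feature: str, setting: str, tumors: Sequence[str]) -> np.ndarray:
        sub = self.df[(self.df["feature"] == feature) & (self.df["setting"] == setting)]
        series = sub.set_index("tumor")["value"]
        missing = [t for t in tumors if t not in series.index]
        if missing:
            raise FeatureTableError(
                f"missing cells for feature {feature!r}, setting {setting!r}, tumors {missing}"
            )
        return series.loc[list(tumors)].to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.df.equals(other.df)


def read_feature_table(path: str | Path, layout: str = "long") -> FeatureTable:
    """Read a delimited-text feature table.

    ``layout='long'``: columns ``tumor,setting,feature,value``.
    ``layout='wide'``: columns ``tumor,setting`` then one column per feature.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "long":
        if df[list(LONG_COLUMNS)].isna().any().any() if set(LONG_COLUMNS) <= set(df.columns) else False:
            bad = df[df.isna().any(axis=1)].iloc[0]
            raise FeatureTableError(f"missing value cell near key {bad.to_dict()}")
        return FeatureTable(df)
    if layout == "wide":
        return FeatureTable.from_wide(df)
    raise FeatureTableError(f"unknown layout {layout!r}; use 'long' or 'wide'")


def write_feature_table(table: FeatureTable, path: str | Path, layout: str = "long") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if layout == "long":
        table.df.to_csv(path, index=False)
    elif layout == "wide":
        table.to_wide().to_csv(path, index=False)
    else:
        raise FeatureTableError(f"unknown layout {layout!r}")


def ingest_s1(
    path: str | Path,
    layout: str = "long",
    column_map: Mapping[str, str] | None = None,
    expect: tuple[int, int, int] | None = (32, 6, 89),
) -> FeatureTable:
    """Ingest the supplementary per-tumor feature workbook exported to CSV.

    The workbook's internal layout is not standardized, so a ``column_map``
    (e.g. ``{"Lesion": "tumor", "Series": "setting"}``) renames whatever
    headers the export uses onto the canonical ones.  Feature names are passed
    through verbatim.  ``expect=(tumors, settings, features)`` enforces the
    expected dimensionality (32 tumors x 6 settings x 89 features for the
    full export); pass ``None`` to skip the check.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    table = FeatureTable(df) if layout == "long" else FeatureTable.from_wide(df)
    if expect is not None:
        dims = (len(table.tumors), len(table.settings), len(table.features))
        if dims != tuple(expect):
            raise FeatureTableError(
                f"expected {expect[0]} tumors x {expect[1]} settings x {expect[2]} features, "
                f"observed {dims[0]} x {dims[1]} x {dims[2]}"
            )
    return table
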