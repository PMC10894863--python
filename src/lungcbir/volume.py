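"""CT volumes and label masks: containers, file I/O, grid checks, resampling.

Volumes are held as numpy arrays indexed ``(x, y, z)`` with physical
coordinates in millimetres derived from ``spacing`` and ``origin`` (LPS).
File I/O and resampling are delegated to SimpleITK, which covers both
NIfTI (``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "LabelMask",
    "DEFAULT_LABEL_SCHEMA",
    "HU_MIN",
    "HU_MAX",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "validate_aligned",
    "resample_isotropic",
]

# Calibrated-HU clamp range applied on load; densitometric thresholds
# (e.g. -950 HU) assume physically plausible attenuation values.
HU_MIN = -1100.0
HU_MAX = 3100.0

#: Label conventions shared by the phantom generator and the quantifiers.
DEFAULT_LABEL_SCHEMA = {
    0: "background",
    1: "right_lung",
    2: "left_lung",
    11: "RUL",
    12: "RML",
    13: "RLL",
    21: "LUL",
    22: "LLL",
    30: "airway_lumen",
    31: "airway_wall",
    40: "vessels",
}

_GRID_TOL_MM = 1e-6


class VolumeFormatError(ValueError):
    """Unreadable file or header without the required geometry."""


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield units with voxel spacing in mm.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values, clamped to ``[HU_MIN, HU_MAX]`` on construction via
        :func:`read_volume` (direct construction does not clamp).
    spacing, origin : tuple of float
        Voxel edge lengths and position of voxel (0, 0, 0), in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise VolumeFormatError(
                f"expected a 3-D grid, got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMask:
    """Integer-labelled grid aligned to a :class:`CTVolume`.

    Label 0 is background; region labels follow ``schema``
    (default :data:`DEFAULT_LABEL_SCHEMA`).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    schema: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_SCHEMA))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D label grid, got shape {self.labels.shape}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region(self, label: int) -> np.ndarray:
        """Boolean mask for one label."""
        return self.labels == label


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK's numpy bridge uses (z, y, x) index order.
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(voxels, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from NIfTI or MetaImage; HU clamped to [-1100, 3100].

    Integer-encoded HU inside the clamp range round-trip bit-exact.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # unrecognised format / corrupt header
        raise VolumeFormatError(f"cannot read volume {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path!r} has {img.GetDimension()} spatial dimensions, need 3"
        )
    arr, spacing, origin = _from_sitk(img)
    arr = np.clip(arr, HU_MIN, HU_MAX).astype(arr.dtype, copy=False)
    return CTVolume(arr, spacing, origin)


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume to NIfTI or MetaImage (chosen by extension)."""
    sitk.WriteImage(_to_sitk(volume.voxels, volume.spacing, volume.origin), os.fspath(path))


def read_mask(path: str | os.PathLike, schema: dict[int, str] | None = None) -> LabelMask:
    """Read an integer label mask; values are cast to the stored integer type."""
    vol = read_volume(path)
    labels = np.rint(vol.voxels).astype(np.int32)
    return LabelMask(labels, vol.spacing, vol.origin,
                     schema=dict(schema or DEFAULT_LABEL_SCHEMA))


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    img = _to_sitk(mask.labels.astype(np.int32), mask.spacing, mask.origin)
    sitk.WriteImage(img, os.fspath(path))


def validate_aligned(volume: CTVolume, mask: LabelMask | CTVolume,
                     tol_mm: float = _GRID_TOL_MM) -> bool:
    """True iff shapes match and spacing/origin agree within ``tol_mm``."""
    if volume.shape != mask.shape:
        return False
    return (
        all(abs(a - b) <= tol_mm for a, b in zip(volume.spacing, mask.spacing))
        and all(abs(a - b) <= tol_mm for a, b in zip(volume.origin, mask.origin))
    )


def resample_isotropic(volume: CTVolume, target_mm: float,
                       interpolation: str = "linear") -> CTVolume:
    """Resample to isotropic ``target_mm`` spacing, preserving physical extent.

    ``interpolation='nearest'`` is mandatory for label masks.  A volume already
    at the target spacing is returned unchanged.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if all(abs(s - target_mm) <= _GRID_TOL_MM for s in volume.spacing):
        return volume

    img = _to_sitk(volume.voxels, volume.spacing, volume.origin)
    new_size = [
        max(1, int(round(n * s / target_mm)))
        for n, s in zip(volume.shape, volume.spacing)
    ]
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target_mm,) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
        True,  # nearest-neighbour extrapolation at the half-voxel fringe
    )
    arr, spacing, origin = _from_sitk(out)
    return CTVolume(arr, spacing, origin)
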