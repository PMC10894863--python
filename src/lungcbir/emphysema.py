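"""Emphysema extent (%LAA-950 / EI) and emphysema size (D-slope).

Extent is lung densitometry: the percentage of lung voxels below -950 HU on
inspiratory CT.  Size is summarised by the D-slope of the 3-D size-based
clustering of the low-attenuation mask: connected low-attenuation components
are reduced to equivalent-sphere diameters, the cumulative count of clusters
at least as large as each observed diameter is plotted against diameter on
log-log axes, and the absolute slope of the least-squares line is reported.
A steeper (larger) D-slope means the emphysema holes are smaller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .regions import EI_VN_REGIONS, region_mask
from .volume import CTVolume, LabelMask, validate_aligned

__all__ = [
    "RegionalValue",
    "ClusterSet",
    "InsufficientDataError",
    "emphysema_index",
    "cluster_emphysema",
    "d_slope",
]

LAA_THRESHOLD_HU = -950.0


class InsufficientDataError(ValueError):
    """Too few distinct observations for the requested fit."""


@dataclass(frozen=True)
class RegionalValue:
    region: str
    value: float


@dataclass
class ClusterSet:
    """Equivalent-sphere diameters (mm) and voxel counts of LAA clusters."""

    diameters_mm: np.ndarray
    voxel_counts: np.ndarray

    def __post_init__(self) -> None:
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)
        self.voxel_counts = np.asarray(self.voxel_counts, dtype=int)
        if self.diameters_mm.shape != self.voxel_counts.shape:
            raise ValueError("diameters and voxel counts must be the same length")

    def __len__(self) -> int:
        return int(self.diameters_mm.size)


def emphysema_index(
    volume: CTVolume,
    lungs: LabelMask,
    threshold_hu: float = LAA_THRESHOLD_HU,
    regions: tuple[str, ...] = EI_VN_REGIONS,
) -> list[RegionalValue]:
    """Percentage of lung voxels strictly below ``threshold_hu``, per region.

    Voxels at exactly the threshold are not counted as low-attenuation.
    """
    if not validate_aligned(volume, lungs):
        raise ValueError("volume and lung mask are not on the same grid")
    laa = volume.voxels < threshold_hu
    out = []
    for region in regions:
        sel = region_mask(lungs, region)
        n = int(sel.sum())
        out.append(RegionalValue(region, 100.0 * int((laa & sel).sum()) / n))
    return out


def cluster_emphysema(
    laa_mask: np.ndarray,
    spacing: tuple[float, float, float],
    connectivity: int = 26,
) -> ClusterSet:
    """Label 3-D connected LAA components and size them as spheres.

    The equivalent diameter of a component of ``V`` mm^3 is ``(6 V / pi)^(1/3)``.
    ``connectivity`` is 26 (full 3-D adjacency, the default) or 6 (faces only).
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    laa_mask = np.asarray(laa_mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    labeled, n = ndimage.label(laa_mask, structure=structure)
    if n == 0:
        return ClusterSet(np.empty(0), np.empty(0, dtype=int))
    counts = np.bincount(labeled.ravel())[1:]
    vol_mm3 = counts * float(np.prod(spacing))
    diameters = np.cbrt(6.0 * vol_mm3 / np.pi)
    order = np.argsort(diameters)
    return ClusterSet(diameters[order], counts[order])


def d_slope(clusters: ClusterSet, min_diameter_mm: float = 0.0) -> float:
    """Absolute log-log slope of the cumulative cluster-size distribution.

    For each distinct diameter ``d`` at or above ``min_diameter_mm``, the
    cumulative count of clusters with diameter >= d is computed, and an
    unweighted least-squares line is fitted to
    ``log10(cumulative count)`` versus ``log10(d)``.  The returned value is
    the absolute slope.  ``min_diameter_mm`` is conventionally set to twice
    the voxel spacing to suppress single-voxel noise clusters.
    """
    d = np.sort(np.asarray(clusters.diameters_mm, dtype=float))
    d = d[d >= min_diameter_mm]
    distinct, first_idx = np.unique(d, return_index=True)
    if distinct.size < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct diameters >= {min_diameter_mm} mm, "
            f"got {distinct.size}"
        )
    cumulative = d.size - first_idx  # clusters with diameter >= each distinct d
    slope = np.polyfit(np.log10(distinct), np.log10(cumulative), 1)[0]
    return float(abs(slope))
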