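"""Airway wall measurement and the Pi10 summary statistic.

A bronchus is measured on the plane perpendicular to its local axis: the
plane is resampled at 0.1 mm (a tenfold magnification relative to typical
sub-millimetre CT), rays are cast outward from the lumen centre, and on each
ray the inner and outer wall boundaries are located by a half-maximum rule —
the inner edge is where attenuation first rises halfway from the lumen
minimum to the wall peak, and the outer edge is where it first falls halfway
from the wall peak back toward the surrounding parenchyma.  This is an
approximation of integral-based wall-edge operators used by commercial
airway tools.

Per-site results are the internal perimeter (Pi, mm) of the inner-edge
polygon and the wall area (WA, mm^2) between the outer and inner polygons.
Pi10 summarises wall thickness across bronchi of different calibres as the
square root of the wall area of a hypothetical airway with an internal
perimeter of 10 mm, read off an ordinary least-squares fit of sqrt(WA)
against Pi over 3rd- to 8th-generation measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .emphysema import InsufficientDataError
from .volume import CTVolume

__all__ = [
    "AirwaySite",
    "AirwayMeasurement",
    "MeasurementFailedError",
    "measure_cross_section",
    "pi10",
]

_RESAMPLE_MM = 0.1  # in-plane sampling step of the magnified cross-section
_MIN_WALL_CONTRAST_HU = 200.0  # peak must rise this far above the lumen floor
_PEAK_WINDOW_MM = 5.0  # search window for the wall peak past the inner rise
_TAIL_WINDOW_MM = 6.0  # window past the peak used to estimate parenchyma HU


class MeasurementFailedError(RuntimeError):
    """Wall edges could not be found on enough rays."""


@dataclass(frozen=True)
class AirwaySite:
    """A measurement location on the airway tree (1 = trachea)."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    generation: int

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        n = float(np.linalg.norm(a))
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"axis must be a unit vector, |axis| = {n}")
        if self.generation < 1:
            raise ValueError("generation must be >= 1")


@dataclass(frozen=True)
class AirwayMeasurement:
    internal_perimeter_mm: float
    wall_area_mm2: float
    generation: int

    @property
    def plausible(self) -> bool:
        """Sanity flag: the wall should be thinner than a solid disc."""
        return np.sqrt(self.wall_area_mm2) < self.internal_perimeter_mm


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def _ray_edges(profile: np.ndarray, step_mm: float) -> tuple[float, float] | None:
    """Return (inner_radius, outer_radius) in mm for one ray, or None on failure."""
    lumen_min = float(profile[: max(3, int(0.5 / step_mm))].min())
    if profile.max() < lumen_min + _MIN_WALL_CONTRAST_HU:
        return None
    # first rise above the global half level locates the wall ...
    half = (lumen_min + float(profile.max())) / 2.0
    above = np.nonzero(profile >= half)[0]
    if above.size == 0:
        return None
    i_rise = int(above[0])
    # ... then the peak is taken locally so a neighbouring structure further
    # out cannot steal it
    win = slice(i_rise, i_rise + int(_PEAK_WINDOW_MM / step_mm))
    peak_idx = i_rise + int(np.argmax(profile[win]))
    wall_peak = float(profile[peak_idx])
    if wall_peak < lumen_min + _MIN_WALL_CONTRAST_HU:
        return None

    inner_thr = (lumen_min + wall_peak) / 2.0
    j = int(np.nonzero(profile[: peak_idx + 1] >= inner_thr)[0][0])
    if j == 0:
        return None  # centre already above threshold: not in a lumen
    frac = (inner_thr - profile[j - 1]) / (profile[j] - profile[j - 1])
    r_in = (j - 1 + frac) * step_mm

    tail = profile[peak_idx : peak_idx + int(_TAIL_WINDOW_MM / step_mm)]
    outer_parenchyma = float(tail.min())
    if wall_peak - outer_parenchyma < _MIN_WALL_CONTRAST_HU / 2:
        return None
    outer_thr = (wall_peak + outer_parenchyma) / 2.0
    below = np.nonzero(profile[peak_idx:] <= outer_thr)[0]
    if below.size == 0:
        return None
    m = peak_idx + int(below[0])
    frac = (profile[m - 1] - outer_thr) / (profile[m - 1] - profile[m])
    r_out = (m - 1 + frac) * step_mm
    return r_in, r_out


def measure_cross_section(
    volume: CTVolume,
    site: AirwaySite,
    n_rays: int = 64,
    max_radius_mm: float = 15.0,
    max_failed_fraction: float = 0.25,
) -> AirwayMeasurement:
    """Measure Pi and WA at one airway site by half-maximum ray casting."""
    axis = np.asarray(site.axis, dtype=float)
    center = np.asarray(site.center, dtype=float)
    u, v = _plane_basis(axis)
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)

    n_steps = int(max_radius_mm / _RESAMPLE_MM)
    radii = np.arange(n_steps) * _RESAMPLE_MM
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    # (ray, step, xyz) sample points in mm, then in fractional voxel indices
    dirs = np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v)
    pts = center[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    idx = (pts - origin) / spacing
    profiles = ndimage.map_coordinates(
        volume.voxels.astype(float),
        idx.reshape(-1, 3).T,
        order=1,
        mode="nearest",
    ).reshape(n_rays, n_steps)

    if profiles[0, 0] >= -500.0:
        raise ValueError(
            f"site centre HU = {profiles[0, 0]:.0f}; not inside an air-filled lumen"
        )

    inner_pts, outer_pts, n_failed = [], [], 0
    for ray in range(n_rays):
        edges = _ray_edges(profiles[ray], _RESAMPLE_MM)
        if edges is None:
            n_failed += 1
            continue
        r_in, r_out = edges
        inner_pts.append(r_in * dirs[ray])
        outer_pts.append(r_out * dirs[ray])
    if n_failed > max_failed_fraction * n_rays:
        raise MeasurementFailedError(
            f"wall edges missing on {n_failed}/{n_rays} rays"
        )

    inner = np.asarray(inner_pts)
    outer = np.asarray(outer_pts)
    pi_mm = float(np.linalg.norm(np.diff(inner, axis=0, append=inner[:1]), axis=1).sum())
    wa = _polygon_area_3d(outer, axis) - _polygon_area_3d(inner, axis)
    return AirwayMeasurement(pi_mm, float(wa), site.generation)


def _polygon_area_3d(points: np.ndarray, normal: np.ndarray) -> float:
    """Shoelace area of a planar polygon given its plane normal."""
    cross_sum = np.cross(points, np.roll(points, -1, axis=0)).sum(axis=0)
    return float(abs(np.dot(cross_sum, normal)) / 2.0)


def pi10(
    measurements: list[AirwayMeasurement],
    generation_range: tuple[int, int] = (3, 8),
) -> float:
    """OLS of sqrt(WA) on Pi over the retained generations, evaluated at 10 mm."""
    lo, hi = generation_range
    kept = [m for m in measurements if lo <= m.generation <= hi]
    if measurements and not kept:
        raise ValueError(
            f"no measurements within generations {generation_range}"
        )
    x = np.array([m.internal_perimeter_mm for m in kept], dtype=float)
    if np.unique(x).size < 2:
        raise InsufficientDataError(
            "need >= 2 measurements with distinct internal perimeters"
        )
    y = np.sqrt([m.wall_area_mm2 for m in kept])
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept + slope * 10.0)
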