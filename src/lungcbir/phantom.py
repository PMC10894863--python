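"""Synthetic lung CT phantoms with known ground truth.

The generator builds a pair of ellipsoidal "lungs" filled with noisy
parenchyma (about -850 HU), then adds the three structures the quantifiers
measure:

* **emphysema** — non-overlapping air-density spheres (-1024 HU) whose
  diameters follow a truncated Pareto (power-law) distribution with a known
  exponent, packed until a target volume fraction is reached;
* **airways** — straight tubes per generation with air lumen (-1000 HU) and
  a soft-tissue wall (0 HU) of known internal radius and wall thickness;
* **vessels** — soft-tissue cylinders (+100 HU) aimed radially outward so
  that each crosses the subpleural surface at the chosen depth exactly once,
  with known cross-sectional areas.

Truth values are reported for the *realized voxel grid* (post-rasterisation),
not the analytic spec, so recovery tests against the quantifiers can be
exact instead of discretisation-limited.

The module also generates tabular stand-ins for a scan database: paired
baseline/follow-up feature vectors with controlled longitudinal noise, and
ordinal similarity ratings from two synthetic readers with controlled
concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from . import vessels as vessels_mod
from .airway import AirwaySite
from .emphysema import ClusterSet, d_slope
from .regions import EI_VN_REGIONS, FEATURE_NAMES, region_mask
from .volume import CTVolume, LabelMask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomGenerationError",
    "emphysema_recovery_spec",
    "generate_lung_phantom",
    "generate_paired_feature_table",
    "generate_reader_ratings",
    "sample_truncated_pareto",
]

PARENCHYMA_HU = -850.0
EMPHYSEMA_HU = -1024.0
LUMEN_HU = -1000.0
WALL_HU = 0.0
VESSEL_HU = 100.0

#: generation -> (internal radius mm, wall thickness mm) for the default tree;
#: thickened walls typical of obstructive airway disease (analytic Pi10 ~ 4.4)
DEFAULT_AIRWAY_GENERATIONS: tuple[tuple[int, float, float], ...] = (
    (3, 3.0, 1.60),
    (4, 2.5, 1.50),
    (5, 2.1, 1.45),
    (6, 1.8, 1.40),
    (7, 1.5, 1.35),
    (8, 1.3, 1.30),
)


class PhantomGenerationError(RuntimeError):
    """The requested phantom cannot be realised (e.g. infeasible packing)."""


@dataclass
class PhantomSpec:
    """Parameters of the synthetic lung phantom.

    Defaults emulate a moderate-emphysema obstructive-lung-disease scan at
    sub-millimetre near-isotropic resolution: a cluster-size power law with
    exponent 3.5 over 3-20 mm holes at a 12% volume fraction (the scale of
    a moderate-emphysema cohort mean EI), a 3rd-8th
    generation airway tree, and forty sub-5-mm2 peripheral vessels per lung
    (plus two above-threshold vessels that must be excluded by the counter).
    """

    spacing_mm: float = 0.7
    lung_semi_axes_mm: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (36.0, 40.0, 48.0),
        (36.0, 40.0, 48.0),
    )
    parenchyma_hu: tuple[float, float] = (PARENCHYMA_HU, 30.0)
    emphysema_fraction: float = 0.12
    cluster_exponent: float = 3.5
    diameter_range_mm: tuple[float, float] = (3.0, 20.0)
    airway_generations: tuple[tuple[int, float, float], ...] = DEFAULT_AIRWAY_GENERATIONS
    airway_length_mm: float = 30.0
    vessels_per_lung: int = 40
    vessel_area_range_mm2: tuple[float, float] = (1.0, 3.5)
    oversize_vessels_per_lung: int = 2
    oversize_vessel_area_mm2: float = 10.0
    vessel_depth_mm: float = 12.0
    lung_gap_mm: float = 12.0
    margin_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.emphysema_fraction < 1.0:
            raise ValueError("emphysema_fraction must be in [0, 1)")
        if self.cluster_exponent <= 0:
            raise ValueError("cluster_exponent must be positive")
        dmin, dmax = self.diameter_range_mm
        if dmin < 2.0 * self.spacing_mm:
            raise ValueError(
                f"min cluster diameter {dmin} mm must be >= 2x spacing "
                f"({2 * self.spacing_mm} mm)"
            )
        if dmax <= dmin:
            raise ValueError("diameter range must be increasing")
        for gen, r, t in self.airway_generations:
            if r <= 0 or t <= 0:
                raise ValueError("airway radii and wall thicknesses must be positive")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class PhantomTruth:
    """Ground truth consistent with the realized phantom grid."""

    true_ei_percent: dict[str, float]
    true_cluster_diameters_mm: list[float]
    drawn_cluster_diameters_mm: list[float]
    true_d_slope: float | None
    true_pi10_mm: dict[str, float]
    true_vessel_counts: dict[str, int]
    true_vn_per_cm2: dict[str, float]
    surface_area_cm2: float
    airway_sites: list[AirwaySite] = field(default_factory=list)
    analytic_airway_points: list[tuple[float, float, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["airway_sites"] = [
            {"center": list(s.center), "axis": list(s.axis), "generation": s.generation}
            for s in self.airway_sites
        ]
        return d


def emphysema_recovery_spec(seed: int = 1) -> PhantomSpec:
    """Emphysema-only phantom sized for cluster-exponent recovery.

    The D-slope estimator (unweighted log-log fit at distinct observed
    diameters) is sensitive to the truncation bend of the cumulative size
    distribution and to voxel quantisation of the smallest holes.  This
    configuration keeps both in check: a 10:1 diameter range makes the bend
    negligible, the smallest holes span 5 voxels, and ~3000 clusters support
    the fit.  Airways and vessels are omitted; they play no role here.
    """
    return PhantomSpec(
        spacing_mm=1.0,
        lung_semi_axes_mm=((79.0, 87.0, 105.0), (79.0, 87.0, 105.0)),
        emphysema_fraction=0.15,
        diameter_range_mm=(5.0, 50.0),
        airway_generations=(),
        vessels_per_lung=0,
        oversize_vessels_per_lung=0,
        seed=seed,
    )


def sample_truncated_pareto(
    n: int, exponent: float, dmin: float, dmax: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of a Pareto(exponent) truncated to [dmin, dmax].

    The survival function on the support is
    ``(d^-k - dmax^-k) / (dmin^-k - dmax^-k)``.
    """
    a, b = dmin ** -exponent, dmax ** -exponent
    u = rng.random(n)
    return (a - u * (a - b)) ** (-1.0 / exponent)


def _ellipsoid_mask(shape, spacing, center, semi_axes):
    grids = [
        ((np.arange(n) + 0.5) * spacing - c) / ax
        for n, c, ax in zip(shape, center, semi_axes)
    ]
    x, y, z = np.ix_(grids[0], grids[1], grids[2])
    return x * x + y * y + z * z <= 1.0


def generate_lung_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, dict[str, LabelMask], PhantomTruth]:
    """Build the phantom volume, its label masks, and the realized truth.

    Returns the HU volume plus three aligned masks: ``lungs`` (lobar labels
    11/12/13/21/22 over the full anatomical lungs), ``airways`` (lumen 30,
    wall 31) and ``vessels`` (40).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.spacing_mm
    (ar, br, cr), (al, bl, cl) = spec.lung_semi_axes_mm

    ext_x = spec.lung_gap_mm + 2 * ar + 2 * al + 2 * spec.margin_mm
    ext_y = 2 * max(br, bl) + 2 * spec.margin_mm
    ext_z = 2 * max(cr, cl) + 2 * spec.margin_mm
    shape = tuple(int(math.ceil(e / s)) for e in (ext_x, ext_y, ext_z))
    cy, cz = ext_y / 2, ext_z / 2
    center_r = (spec.margin_mm + ar, cy, cz)
    center_l = (ext_x - spec.margin_mm - al, cy, cz)

    right = _ellipsoid_mask(shape, s, center_r, (ar, br, cr))
    left = _ellipsoid_mask(shape, s, center_l, (al, bl, cl))

    lungs = np.zeros(shape, dtype=np.int16)
    zc = (np.arange(shape[2]) + 0.5) * s
    # lobar split by height: right upper/middle/lower at 35/20/45%,
    # left upper/lower at 45/55% (z grows caudally->cranially here)
    zr = (zc - (center_r[2] - cr)) / (2 * cr)
    lobe_r = np.where(zr >= 0.65, 11, np.where(zr >= 0.45, 12, 13)).astype(np.int16)
    lungs[right] = np.broadcast_to(lobe_r[None, None, :], shape)[right]
    zl = (zc - (center_l[2] - cl)) / (2 * cl)
    lobe_l = np.where(zl >= 0.55, 21, 22).astype(np.int16)
    lungs[left] = np.broadcast_to(lobe_l[None, None, :], shape)[left]

    hu = np.zeros(shape, dtype=np.float32)
    lung_any = lungs > 0
    mean_hu, sd_hu = spec.parenchyma_hu
    if sd_hu > 0:
        hu[lung_any] = rng.normal(mean_hu, sd_hu, int(lung_any.sum())).astype(np.float32)
    else:
        hu[lung_any] = mean_hu

    coords_mm = [(np.arange(n) + 0.5) * s for n in shape]
    airway_labels = np.zeros(shape, dtype=np.int16)
    sites: list[AirwaySite] = []
    analytic_points: list[tuple[float, float, int]] = []
    for lung_idx, (center, axes) in enumerate(
        [(center_r, (ar, br, cr)), (center_l, (al, bl, cl))]
    ):
        _place_airways(spec, hu, airway_labels, coords_mm, center, axes,
                       sites, analytic_points, lung_idx)

    dist = ndimage.distance_transform_edt(lung_any, sampling=(s, s, s))

    vessel_labels = np.zeros(shape, dtype=np.int16)
    vessel_records: list[tuple[str, float]] = []  # (region, analytic area)
    for center, axes in [(center_r, (ar, br, cr)), (center_l, (al, bl, cl))]:
        _place_vessels(spec, rng, hu, vessel_labels, airway_labels, lungs,
                       dist, coords_mm, center, axes, vessel_records)

    occupied = (airway_labels > 0) | (vessel_labels > 0)
    emph_mask, realized_counts, drawn = _pack_emphysema(
        spec, rng, hu, lung_any, occupied, dist, coords_mm
    )

    volume = CTVolume(hu, (s, s, s))
    masks = {
        "lungs": LabelMask(lungs, (s, s, s)),
        "airways": LabelMask(airway_labels, (s, s, s)),
        "vessels": LabelMask(vessel_labels, (s, s, s)),
    }
    truth = _compile_truth(
        spec, volume, masks, realized_counts, drawn, sites, analytic_points,
        vessel_records,
    )
    return volume, masks, truth


def _place_airways(spec, hu, airway_labels, coords_mm, center, axes,
                   sites, analytic_points, lung_idx) -> None:
    if not spec.airway_generations:
        return
    a, b, c = axes
    s = spec.spacing_mm
    half_len = spec.airway_length_mm / 2
    n_tubes = len(spec.airway_generations)
    # ring radius chosen so adjacent tubes keep >= 4 mm of parenchyma between
    # their outer walls (rays from one tube must not run into its neighbour)
    outer = [r + t for _, r, t in spec.airway_generations]
    if n_tubes > 1:
        worst = max(outer[i] + outer[(i + 1) % n_tubes] for i in range(n_tubes))
        ring = (worst + 4.0) / (2.0 * math.sin(math.pi / n_tubes))
    else:
        ring = 0.35 * min(a, b)
    xs, ys, zs = coords_mm
    for i, (gen, r_in, t) in enumerate(spec.airway_generations):
        r_out = r_in + t
        theta = 2 * np.pi * i / n_tubes
        x0 = center[0] + ring * np.cos(theta)
        y0 = center[1] + ring * np.sin(theta)
        rho_max = ring + r_out + 2.0
        if (rho_max / min(a, b)) ** 2 + ((half_len + 2.0) / c) ** 2 > 1.0:
            raise PhantomGenerationError(
                f"airway generation {gen} (outer radius {r_out:.1f} mm) does "
                f"not fit inside lung semi-axes {axes}"
            )
        sl = _bbox(coords_mm, (x0, y0, center[2]), (r_out + s, r_out + s, half_len))
        # partial-volume (supersampled) in-plane rasterisation: CT blurs thin
        # walls, and the half-maximum edge rule is only accurate on blurred
        # edges, so a crisp binary tube would be unrealistically hard to measure
        ss_n = 4
        off = ((np.arange(ss_n) + 0.5) / ss_n - 0.5) * s
        f_lumen = np.zeros((sl[0].stop - sl[0].start, sl[1].stop - sl[1].start))
        f_wall = np.zeros_like(f_lumen)
        for ox in off:
            for oy in off:
                dx = xs[sl[0]][:, None] + ox - x0
                dy = ys[sl[1]][None, :] + oy - y0
                rho2 = dx * dx + dy * dy
                f_lumen += rho2 <= r_in**2
                f_wall += (rho2 > r_in**2) & (rho2 <= r_out**2)
        f_lumen /= ss_n**2
        f_wall /= ss_n**2
        dz = zs[sl[2]][None, None, :] - center[2]
        inside_z = (np.abs(dz) <= half_len)[0, 0]
        fl3 = f_lumen[:, :, None] * inside_z[None, None, :]
        fw3 = f_wall[:, :, None] * inside_z[None, None, :]
        sub = hu[sl]
        hu[sl] = fl3 * LUMEN_HU + fw3 * WALL_HU + (1.0 - fl3 - fw3) * sub
        covered = fl3 + fw3 >= 0.5
        airway_labels[sl][covered & (fl3 >= fw3)] = 30
        airway_labels[sl][covered & (fl3 < fw3)] = 31
        sites.append(AirwaySite((x0, y0, center[2]), (0.0, 0.0, 1.0), gen))
        pi_mm = 2 * np.pi * r_in
        wa = np.pi * (r_out**2 - r_in**2)
        analytic_points.append((pi_mm, wa, gen))


def _bbox(coords_mm, center, half_extents):
    out = []
    for coord, c, h in zip(coords_mm, center, half_extents):
        lo = np.searchsorted(coord, c - h) - 1
        hi = np.searchsorted(coord, c + h) + 1
        out.append(slice(max(0, lo), min(coord.size, hi)))
    return tuple(out)


def _place_vessels(spec, rng, hu, vessel_labels, airway_labels, lungs, dist,
                   coords_mm, center, axes, vessel_records) -> None:
    n_total = spec.vessels_per_lung + spec.oversize_vessels_per_lung
    if n_total == 0:
        return
    areas = np.concatenate([
        rng.uniform(*spec.vessel_area_range_mm2, spec.vessels_per_lung),
        np.full(spec.oversize_vessels_per_lung, spec.oversize_vessel_area_mm2),
    ])
    depth = spec.vessel_depth_mm
    s = spec.spacing_mm
    xs, ys, zs = coords_mm
    min_angle = 0.20
    directions: list[np.ndarray] = []
    placed = 0
    attempts = 0
    c_arr = np.asarray(center)
    while placed < n_total:
        attempts += 1
        if attempts > 200 * n_total:
            raise PhantomGenerationError("cannot place radial vessels")
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        if directions and min(float(np.arccos(np.clip(np.dot(w, d), -1, 1)))
                              for d in directions) < min_angle:
            continue
        # walk outward along the ray; the depth map decreases monotonically
        t_grid = np.arange(0.0, 2 * max(axes), 0.5)
        pts = c_arr[None, :] + t_grid[:, None] * w[None, :]
        idx = (pts / s - 0.5).T
        d_along = ndimage.map_coordinates(dist, idx, order=1, mode="constant")
        # restrict to the first contiguous in-lung segment of the ray: past
        # the pleura the ray may re-enter the other lung and would otherwise
        # deposit spurious extra crossings there
        exit_i = np.nonzero(d_along <= 0)[0]
        limit = int(exit_i[0]) if exit_i.size else d_along.size
        d_seg = d_along[:limit]
        if d_seg.size == 0:
            continue
        start_c = np.nonzero(d_seg < depth + 6.0)[0]
        end_c = np.nonzero(d_seg >= max(1.5, depth - 6.0))[0]
        if start_c.size == 0 or end_c.size == 0:
            continue
        t0, t1 = t_grid[start_c[0]], t_grid[end_c[-1]]
        if t1 <= t0:
            continue
        # crossing point: where the ray reaches the target depth
        cross_i = np.nonzero(d_seg <= depth)[0]
        if cross_i.size == 0:
            continue
        p_cross = pts[cross_i[0]]
        region_label = _label_at(lungs, p_cross, s)
        if region_label == 0:
            continue
        # avoid the lobe-boundary planes so truth regions are unambiguous
        if _near_lobe_boundary(lungs, p_cross, s, margin_mm=3.0):
            continue
        radius = math.sqrt(areas[placed] / math.pi)
        if _rasterize_cylinder(hu, vessel_labels, airway_labels, coords_mm,
                               c_arr + t0 * w, c_arr + t1 * w, radius):
            directions.append(w)
            vessel_records.append((_REGION_OF_LABEL[region_label], float(areas[placed])))
            placed += 1


_REGION_OF_LABEL = {11: "RUL", 12: "RML", 13: "RLL", 21: "LUL", 22: "LLL",
                    1: "right", 2: "left"}


def _label_at(lungs, point_mm, s):
    idx = tuple(int(p / s) for p in point_mm)
    if any(i < 0 or i >= n for i, n in zip(idx, lungs.shape)):
        return 0
    return int(lungs[idx])


def _near_lobe_boundary(lungs, point_mm, s, margin_mm):
    here = _label_at(lungs, point_mm, s)
    for dz in (-margin_mm, margin_mm):
        other = _label_at(lungs, point_mm + np.array([0, 0, dz]), s)
        if other not in (0, here):
            return True
    return False


def _rasterize_cylinder(hu, vessel_labels, airway_labels, coords_mm, p0, p1,
                        radius) -> bool:
    """Paint a finite cylinder; refuse (return False) if it touches an airway."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = tuple(
        slice(max(0, np.searchsorted(c, l) - 1), min(c.size, np.searchsorted(c, h) + 1))
        for c, l, h in zip(coords_mm, lo, hi)
    )
    xs, ys, zs = (c[s_] for c, s_ in zip(coords_mm, sl))
    px = xs[:, None, None]
    py = ys[None, :, None]
    pz = zs[None, None, :]
    axis = p1 - p0
    length2 = float(np.dot(axis, axis))
    tx = ((px - p0[0]) * axis[0] + (py - p0[1]) * axis[1] + (pz - p0[2]) * axis[2]) / length2
    tx = np.clip(tx, 0.0, 1.0)
    qx = p0[0] + tx * axis[0] - px
    qy = p0[1] + tx * axis[1] - py
    qz = p0[2] + tx * axis[2] - pz
    inside = qx * qx + qy * qy + qz * qz <= radius * radius
    # a thin cylinder can rasterize with diagonal gaps; a 6-connected core
    # line along the axis guarantees every crossing of a 6-neighbour-defined
    # iso-shell intersects the vessel
    spacing = float(coords_mm[0][1] - coords_mm[0][0]) if coords_mm[0].size > 1 else 1.0
    n_steps = max(2, int(np.linalg.norm(axis) / (0.25 * spacing)))
    samples = p0[None, :] + np.linspace(0, 1, n_steps)[:, None] * axis[None, :]
    vox = np.round(samples / spacing - 0.5).astype(int)
    line = [vox[0]]
    for v in vox[1:]:
        cur = line[-1]
        while not np.array_equal(cur, v):
            step = np.zeros(3, dtype=int)
            ax_i = int(np.argmax(np.abs(v - cur)))
            step[ax_i] = int(np.sign(v[ax_i] - cur[ax_i]))
            cur = cur + step
            line.append(cur)
    shape = hu.shape
    line = [tuple(v) for v in line
            if all(0 <= v[i] < shape[i] for i in range(3))]
    if (airway_labels[sl][inside] > 0).any() or any(
        airway_labels[v] > 0 for v in line
    ):
        return False
    hu[sl][inside] = VESSEL_HU
    vessel_labels[sl][inside] = 40
    for v in line:
        hu[v] = VESSEL_HU
        vessel_labels[v] = 40
    return True


def _pack_emphysema(spec, rng, hu, lung_any, occupied, dist, coords_mm):
    """Non-overlapping sphere packing by rejection sampling with a retry cap."""
    s = spec.spacing_mm
    voxel_vol = s**3
    n_lung = int((lung_any & ~occupied).sum())
    target_vol = spec.emphysema_fraction * n_lung * voxel_vol
    emph = np.zeros_like(lung_any)
    if target_vol <= 0:
        return emph, [], np.empty(0)

    dmin, dmax = spec.diameter_range_mm
    draws = []
    total = 0.0
    while total < target_vol:
        d = float(sample_truncated_pareto(1, spec.cluster_exponent, dmin, dmax, rng)[0])
        draws.append(d)
        total += np.pi / 6 * d**3
    draws = np.asarray(draws)
    order = np.argsort(draws)[::-1]  # place large spheres first

    occ_dist = ndimage.distance_transform_edt(~occupied, sampling=(s, s, s))
    shape = lung_any.shape
    # surface gap > sqrt(3) * spacing so rasterized spheres can never be
    # 26-connected and the cluster count stays exact
    gap = math.sqrt(3) * s + 0.2

    centers = np.empty((draws.size, 3))
    radii = np.empty(draws.size)
    placed = 0
    attempts = 0
    max_attempts = 10 * draws.size * 25
    xs, ys, zs = coords_mm
    # candidate centers restricted to voxels that can legally host the
    # current radius (deep enough in the lung, 4 mm clear of airways and
    # vessels so wall-edge rays see clean parenchyma just outside the wall);
    # the eligibility set is refreshed per 1-mm radius bucket as spheres shrink
    dist_flat = dist.ravel()
    occ_flat = occ_dist.ravel()
    lung_flat_mask = lung_any.ravel()
    bucket = None
    eligible = None
    for d in draws[order]:
        r = d / 2
        r_bucket = math.ceil(r)
        if r_bucket != bucket:
            bucket = r_bucket
            eligible = np.flatnonzero(
                lung_flat_mask
                & (dist_flat >= bucket + 1.0)
                & (occ_flat >= bucket + 4.0)
            )
            if eligible.size == 0:
                raise PhantomGenerationError(
                    f"no room for a {d:.1f} mm emphysema cluster in this lung"
                )
        ok = False
        while not ok:
            attempts += 1
            if attempts > max_attempts:
                raise PhantomGenerationError(
                    f"emphysema packing infeasible: placed {placed}/{draws.size} "
                    f"spheres for fraction {spec.emphysema_fraction}"
                )
            flat = int(eligible[rng.integers(eligible.size)])
            ijk = np.unravel_index(flat, shape)
            c = np.array([xs[ijk[0]], ys[ijk[1]], zs[ijk[2]]])
            c += rng.uniform(-s / 2, s / 2, 3)
            if placed:
                sep = np.linalg.norm(centers[:placed] - c, axis=1) - radii[:placed]
                if float(sep.min()) < r + gap:
                    continue
            ok = True
        centers[placed] = c
        radii[placed] = r
        placed += 1

    realized_counts = []
    for c, r in zip(centers, radii):
        sl = _bbox(coords_mm, c, (r, r, r))
        dx = xs[sl[0]][:, None, None] - c[0]
        dy = ys[sl[1]][None, :, None] - c[1]
        dz = zs[sl[2]][None, None, :] - c[2]
        inside = dx * dx + dy * dy + dz * dz <= r * r
        realized_counts.append(int(inside.sum()))
        hu[sl][inside] = EMPHYSEMA_HU
        emph[sl][inside] = True
    return emph, realized_counts, draws


def _compile_truth(spec, volume, masks, realized_counts, drawn, sites,
                   analytic_points, vessel_records) -> PhantomTruth:
    s = spec.spacing_mm
    lungs = masks["lungs"]
    carved = lungs.labels.copy()
    carved[masks["airways"].labels > 0] = 0
    carved_mask = LabelMask(carved, lungs.spacing, lungs.origin)
    laa = volume.voxels < -950.0

    true_ei = {}
    for region in EI_VN_REGIONS:
        sel = region_mask(carved_mask, region)
        true_ei[region] = 100.0 * float((laa & sel).sum()) / float(sel.sum())

    counts = np.asarray(realized_counts, dtype=float)
    diam = np.sort(np.cbrt(6.0 * counts * s**3 / np.pi)) if counts.size else np.empty(0)
    true_ds = None
    if diam.size:
        try:
            true_ds = d_slope(ClusterSet(diam, counts[np.argsort(diam)]),
                              min_diameter_mm=2 * s)
        except ValueError:
            true_ds = None

    true_pi10: dict[str, float] = {}
    if analytic_points:
        pts = np.asarray([(p, math.sqrt(w)) for p, w, _ in analytic_points])
        half = len(analytic_points) // 2  # first half right lung, second left
        groups = {"whole": pts, "right": pts[:half], "left": pts[half:]}
        for region, g in groups.items():
            if len(g) >= 2 and np.unique(g[:, 0]).size >= 2:
                slope, intercept = np.polyfit(g[:, 0], g[:, 1], 1)
                true_pi10[region] = float(intercept + slope * 10.0)

    lobe_counts = {r: 0 for r in ("RUL", "RML", "RLL", "LUL", "LLL")}
    for region, area in vessel_records:
        if area < 5.0 and region in lobe_counts:
            lobe_counts[region] += 1
    vessel_counts = dict(lobe_counts)
    vessel_counts["right"] = sum(lobe_counts[r] for r in ("RUL", "RML", "RLL"))
    vessel_counts["left"] = sum(lobe_counts[r] for r in ("LUL", "LLL"))
    vessel_counts["whole"] = vessel_counts["right"] + vessel_counts["left"]

    true_vn = {}
    surface_area = 0.0
    try:
        surface = vessels_mod.peripheral_surface(lungs, spec.vessel_depth_mm)
        surface_area = surface.area_cm2
        total_shell = surface.n_voxels
        for region in EI_VN_REGIONS:
            shell_r = int((surface.shell & region_mask(lungs, region)).sum())
            if shell_r:
                area_r = surface.area_cm2 * shell_r / total_shell
                true_vn[region] = vessel_counts[region] / area_r
            else:
                true_vn[region] = 0.0
    except vessels_mod.EmptySurfaceError:
        true_vn = {region: 0.0 for region in EI_VN_REGIONS}

    return PhantomTruth(
        true_ei_percent=true_ei,
        true_cluster_diameters_mm=[float(d) for d in diam],
        drawn_cluster_diameters_mm=[float(d) for d in np.sort(drawn)],
        true_d_slope=true_ds,
        true_pi10_mm=true_pi10,
        true_vessel_counts=vessel_counts,
        true_vn_per_cm2=true_vn,
        surface_area_cm2=surface_area,
        airway_sites=sites,
        analytic_airway_points=analytic_points,
    )


# ---------------------------------------------------------------------------
# tabular generators


#: whole-lung feature marginals of a plausible obstructive-lung-disease
#: database: mean, SD, and lower clip (EI in %, D-slope and Pi10 in their
#: natural units, VN per cm^2)
FEATURE_MARGINALS = {
    "EI": (12.2, 13.1, 0.1),
    "Dslope": (5.1, 1.5, 0.5),
    "Pi10": (4.0, 0.8, 0.5),
    "VN": (0.6, 0.1, 0.05),
}

#: default longitudinal noise SD per category for follow-up scans; small
#: relative to between-patient spread, emulating stable disease over ~3 years
DEFAULT_NOISE_SD = {"EI": 1.0, "Dslope": 0.2, "Pi10": 0.15, "VN": 0.03}

_LOBE_JITTER_SD = 0.25  # lognormal sd of lobar values around the whole-lung value
_SIDE_JITTER_SD = 0.08


def _draw_scan_features(rng: np.random.Generator) -> dict[str, float]:
    row: dict[str, float] = {}
    for cat in ("EI", "VN"):
        mean, sd, lo = FEATURE_MARGINALS[cat]
        whole = max(lo, rng.normal(mean, sd))
        lobes = {r: whole * math.exp(rng.normal(0.0, _LOBE_JITTER_SD))
                 for r in ("RUL", "RML", "RLL", "LUL", "LLL")}
        right = (lobes["RUL"] + lobes["RML"] + lobes["RLL"]) / 3
        left = (lobes["LUL"] + lobes["LLL"]) / 2
        row.update({f"{cat}_whole": (3 * right + 2 * left) / 5,
                    f"{cat}_right": right, f"{cat}_left": left})
        row.update({f"{cat}_{r}": v for r, v in lobes.items()})
    for cat in ("Dslope", "Pi10"):
        mean, sd, lo = FEATURE_MARGINALS[cat]
        whole = max(lo, rng.normal(mean, sd))
        right = whole * math.exp(rng.normal(0.0, _SIDE_JITTER_SD))
        left = whole * math.exp(rng.normal(0.0, _SIDE_JITTER_SD))
        row.update({f"{cat}_whole": whole, f"{cat}_right": right,
                    f"{cat}_left": left})
    return row


def generate_paired_feature_table(
    n_pairs: int,
    n_singletons: int,
    noise_sd: float | dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic feature-vector database with baseline/follow-up pairs.

    ``n_pairs`` baseline scans each have a follow-up "query" scan equal to
    the baseline plus Normal(0, noise_sd) longitudinal noise truncated at
    zero; ``n_singletons`` independent scans fill out the database.
    ``noise_sd`` may be a single SD for every feature or a per-category map
    (default :data:`DEFAULT_NOISE_SD`).  Columns: ``scan_id``, ``pair_id``,
    ``role`` (baseline / singleton / query) and the 22 feature names.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if noise_sd is None:
        noise_sd = dict(DEFAULT_NOISE_SD)
    if isinstance(noise_sd, (int, float)):
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        noise_sd = {cat: float(noise_sd) for cat in FEATURE_MARGINALS}
    rng = np.random.default_rng(seed)

    rows = []
    for i in range(n_pairs):
        base = _draw_scan_features(rng)
        pair_id = f"P{i:04d}"
        rows.append({"scan_id": f"{pair_id}B", "pair_id": pair_id,
                     "role": "baseline", **base})
        follow = {
            name: max(0.0, v + rng.normal(0.0, noise_sd[name.split("_", 1)[0]]))
            for name, v in base.items()
        }
        rows.append({"scan_id": f"{pair_id}F", "pair_id": pair_id,
                     "role": "query", **follow})
    for i in range(n_singletons):
        rows.append({"scan_id": f"S{i:04d}", "pair_id": "",
                     "role": "singleton", **_draw_scan_features(rng)})
    return pd.DataFrame(rows, columns=["scan_id", "pair_id", "role", *FEATURE_NAMES])


def generate_reader_ratings(
    results,
    pairs: dict[str, str] | None = None,
    concordance: float = 0.6,
    seed: int = 0,
    noise_sd: float = 1.2,
) -> pd.DataFrame:
    """Ordinal 1-5 similarity scores from two synthetic readers.

    Each retrieved scan gets a latent similarity that decreases with its
    retrieval distance (and is maximal for the query's own baseline pair);
    ``concordance`` in [0, 1] controls how much of the readers' noise is
    shared: 1 makes the two readers identical, 0 makes their scores
    independent of each other and of the retrieval distance.
    """
    if not results:
        raise ValueError("results must be non-empty")
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    d_max = max(
        (item[1] for res in results for item in res.ranked), default=1.0
    ) or 1.0
    records = []
    for res in results:
        for rank, (scan_id, dist, _) in enumerate(res.ranked, start=1):
            if pairs and pairs.get(res.query_id) == scan_id:
                mu = 5.0
            else:
                mu = 1.0 + 4.0 * (1.0 - dist / d_max)
            z_shared = rng.normal()
            for reader in (1, 2):
                z = math.sqrt(concordance) * z_shared + math.sqrt(
                    1.0 - concordance
                ) * rng.normal()
                latent = concordance * mu + (1.0 - concordance) * 3.0 + noise_sd * z
                score = int(np.clip(round(latent), 1, 5))
                records.append(
                    {"query_id": res.query_id, "rank": rank, "reader": reader,
                     "score": score}
                )
    return pd.DataFrame(records)
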