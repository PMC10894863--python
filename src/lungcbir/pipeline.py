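"""Per-scan feature extraction: one CT volume + masks -> 22 features.

Dispatches the four quantifiers and assembles their regional outputs into
the feature-vector layout used by the retrieval index.  Lung label masks
may include airway voxels; they are carved out before densitometry so the
air-filled lumen does not masquerade as emphysema.
"""

from __future__ import annotations

import numpy as np

from .airway import AirwaySite, measure_cross_section, pi10
from .emphysema import cluster_emphysema, d_slope, emphysema_index
from .regions import DSLOPE_PI10_REGIONS, EI_VN_REGIONS, FEATURE_NAMES, region_mask
from .vessels import count_peripheral_vessels, peripheral_surface
from .volume import CTVolume, LabelMask, validate_aligned

__all__ = ["quantify_scan", "carve_lungs"]

_RIGHT_LABELS = {1, 11, 12, 13}


def carve_lungs(lungs: LabelMask, airways: LabelMask | None) -> LabelMask:
    """Lung labels with airway (lumen + wall) voxels removed."""
    if airways is None:
        return lungs
    carved = lungs.labels.copy()
    carved[airways.labels > 0] = 0
    return LabelMask(carved, lungs.spacing, lungs.origin, schema=lungs.schema)


def quantify_scan(
    volume: CTVolume,
    lungs: LabelMask,
    airways: LabelMask | None = None,
    vessels: LabelMask | None = None,
    sites: list[AirwaySite] | None = None,
    threshold_hu: float = -950.0,
    depth_mm: float = 12.0,
    max_area_mm2: float = 5.0,
    connectivity: int = 26,
) -> dict[str, float]:
    """Compute all 22 quantitative features for one scan.

    Requires a lung (lobar) mask; vessel masks and airway measurement sites
    are needed for the VN and Pi10 categories respectively.  Raises on
    misaligned masks or missing inputs rather than returning partial rows.
    """
    for name, mask in (("lungs", lungs), ("airways", airways), ("vessels", vessels)):
        if mask is not None and not validate_aligned(volume, mask):
            raise ValueError(f"{name} mask is not aligned with the volume")
    if vessels is None:
        raise ValueError("a vessel mask is required for the VN features")
    if not sites:
        raise ValueError("airway measurement sites are required for Pi10")

    out: dict[str, float] = {}
    carved = carve_lungs(lungs, airways)

    for rv in emphysema_index(volume, carved, threshold_hu, EI_VN_REGIONS):
        out[f"EI_{rv.region}"] = rv.value

    min_diam = 2.0 * float(np.mean(volume.spacing))
    laa = volume.voxels < threshold_hu
    for region in DSLOPE_PI10_REGIONS:
        sel = region_mask(carved, region)
        clusters = cluster_emphysema(laa & sel, volume.spacing, connectivity)
        out[f"Dslope_{region}"] = d_slope(clusters, min_diameter_mm=min_diam)

    measurements = {"whole": [], "right": [], "left": []}
    for site in sites:
        m = measure_cross_section(volume, site)
        side = _site_side(lungs, site)
        measurements["whole"].append(m)
        if side:
            measurements[side].append(m)
    for region in DSLOPE_PI10_REGIONS:
        out[f"Pi10_{region}"] = pi10(measurements[region])

    surface = peripheral_surface(lungs, depth_mm)
    for rv in count_peripheral_vessels(vessels, surface, lungs, max_area_mm2):
        out[f"VN_{rv.region}"] = rv.value

    assert set(out) == set(FEATURE_NAMES)
    return out


def _site_side(lungs: LabelMask, site: AirwaySite) -> str | None:
    idx = tuple(
        int((c - o) / s)
        for c, o, s in zip(site.center, lungs.origin, lungs.spacing)
    )
    if any(i < 0 or i >= n for i, n in zip(idx, lungs.shape)):
        return None
    label = int(lungs.labels[idx])
    if label == 0:
        return None
    return "right" if label in _RIGHT_LABELS else "left"
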