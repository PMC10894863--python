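"""Lung region vocabulary and the 22-feature layout of a scan's feature vector.

Four feature categories describe one scan's obstructive-lung-disease
phenotype: emphysema extent (EI, i.e. %LAA-950) and peripheral vessel count
(VN) over whole lung / right / left / five lobes, and emphysema size
(D-slope) and airway wall thickness (Pi10) over whole / right / left.
"""

from __future__ import annotations

import numpy as np

from .volume import LabelMask

__all__ = [
    "EI_VN_REGIONS",
    "DSLOPE_PI10_REGIONS",
    "FEATURE_NAMES",
    "FEATURE_CATEGORIES",
    "CATEGORY_NAMES",
    "region_mask",
]

EI_VN_REGIONS = ("whole", "right", "left", "RUL", "RML", "RLL", "LUL", "LLL")
DSLOPE_PI10_REGIONS = ("whole", "right", "left")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"EI_{r}" for r in EI_VN_REGIONS]
    + [f"Dslope_{r}" for r in DSLOPE_PI10_REGIONS]
    + [f"Pi10_{r}" for r in DSLOPE_PI10_REGIONS]
    + [f"VN_{r}" for r in EI_VN_REGIONS]
)

#: feature name -> category, the grouping used for per-category cosine distances
FEATURE_CATEGORIES: dict[str, str] = {name: name.split("_", 1)[0] for name in FEATURE_NAMES}

CATEGORY_NAMES = ("EI", "Dslope", "Pi10", "VN")

# Region -> the label values that compose it (lungs may be stored either as
# whole-lung labels 1/2 or as lobar labels).
_REGION_LABELS = {
    "whole": (1, 2, 11, 12, 13, 21, 22),
    "right": (1, 11, 12, 13),
    "left": (2, 21, 22),
    "RUL": (11,),
    "RML": (12,),
    "RLL": (13,),
    "LUL": (21,),
    "LLL": (22,),
}


def region_mask(lungs: LabelMask, region: str) -> np.ndarray:
    """Boolean voxel mask for a named lung region.

    Raises ``KeyError`` for an unknown region name and ``ValueError`` when the
    requested region is empty on this mask.
    """
    try:
        labels = _REGION_LABELS[region]
    except KeyError:
        raise KeyError(
            f"unknown region {region!r}; expected one of {sorted(_REGION_LABELS)}"
        ) from None
    out = np.isin(lungs.labels, labels)
    if not out.any():
        raise ValueError(f"region {region!r} is empty in this mask")
    return out
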