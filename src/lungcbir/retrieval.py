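"""The CBIR core: feature normalization, cosine distances, top-k retrieval.

A scan is represented by 22 quantitative features in four categories
(emphysema extent, emphysema size, airway wall thickness, peripheral
vessels).  Every feature is normalized by its 95th percentile over the
database; similarity between two scans is measured per category as the
cosine distance between the category sub-vectors, and the four category
distances are combined (by default as their unweighted mean) into a single
ranking distance.  The most similar scans have the least distance.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import CATEGORY_NAMES, FEATURE_CATEGORIES, FEATURE_NAMES

__all__ = [
    "FeatureVector",
    "RetrievalIndex",
    "RetrievalResult",
    "IndexFormatError",
    "build_index",
    "query",
    "save_index",
    "load_index",
]

_CATEGORY_SLICES = {
    cat: np.array([i for i, f in enumerate(FEATURE_NAMES) if FEATURE_CATEGORIES[f] == cat])
    for cat in CATEGORY_NAMES
}


class IndexFormatError(ValueError):
    """Index file does not follow the expected JSON schema."""


@dataclass(frozen=True)
class FeatureVector:
    """One scan's 22 named feature values (all finite and non-negative)."""

    scan_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} feature values, got shape {v.shape}"
            )
        if not np.isfinite(v).all():
            raise ValueError(f"scan {self.scan_id}: non-finite feature values")
        if (v < 0).any():
            raise ValueError(f"scan {self.scan_id}: negative feature values")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_mapping(cls, scan_id: str, mapping) -> "FeatureVector":
        try:
            vals = [mapping[name] for name in FEATURE_NAMES]
        except KeyError as exc:
            raise ValueError(f"scan {scan_id}: missing feature {exc}") from None
        return cls(scan_id, np.asarray(vals, dtype=float))


@dataclass
class RetrievalIndex:
    """Normalized feature database plus its per-feature 95th percentiles."""

    scan_ids: list[str]
    normalized: np.ndarray  # (n_scans, 22)
    normalizers: np.ndarray  # (22,)
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(set(self.scan_ids)) != len(self.scan_ids):
            raise ValueError("duplicate scan_id in index")
        if (np.asarray(self.normalizers) <= 0).any():
            raise ValueError("normalizers must be positive")

    def __len__(self) -> int:
        return len(self.scan_ids)


@dataclass
class RetrievalResult:
    """Ranked retrievals for one query, ascending by combined distance."""

    query_id: str
    ranked: list[tuple[str, float, dict[str, float]]] = field(default_factory=list)

    @property
    def scan_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.ranked]


def _as_feature_vectors(features) -> list[FeatureVector]:
    if isinstance(features, pd.DataFrame):
        return [
            FeatureVector.from_mapping(str(row["scan_id"]), row)
            for _, row in features.iterrows()
        ]
    return [
        fv if isinstance(fv, FeatureVector) else FeatureVector.from_mapping(*fv)
        for fv in features
    ]


def build_index(features) -> RetrievalIndex:
    """Build the retrieval index from feature vectors (or a feature table).

    The per-feature normalizer is the 95th percentile over the database
    (linear interpolation between order statistics); a feature that is
    constant at zero gets a normalizer of 1 so its normalized values stay 0.
    """
    fvs = _as_feature_vectors(features)
    if len(fvs) < 2:
        raise ValueError("need at least 2 feature vectors to build an index")
    ids = [fv.scan_id for fv in fvs]
    raw = np.stack([fv.values for fv in fvs])
    normalizers = np.percentile(raw, 95.0, axis=0)
    zero = normalizers == 0
    if zero.any():
        names = [FEATURE_NAMES[i] for i in np.nonzero(zero)[0]]
        warnings.warn(
            f"features constant at zero, normalizer set to 1: {names}",
            stacklevel=2,
        )
        normalizers = np.where(zero, 1.0, normalizers)
    return RetrievalIndex(ids, raw / normalizers, normalizers)


def _category_distances(u: np.ndarray, entries: np.ndarray) -> dict[str, np.ndarray]:
    """Cosine distance per category between one query and all entries.

    A zero-norm sub-vector yields distance 0 against another zero sub-vector
    and 1 against anything else.
    """
    out = {}
    for cat, cols in _CATEGORY_SLICES.items():
        uc = u[cols]
        vc = entries[:, cols]
        nu = np.linalg.norm(uc)
        nv = np.linalg.norm(vc, axis=1)
        d = np.ones(len(entries))
        both = (nu > 0) & (nv > 0)
        if nu > 0:
            cos = (vc[both] @ uc) / (nv[both] * nu)
            d[both] = 1.0 - np.clip(cos, -1.0, 1.0)
        d[(nu == 0) & (nv == 0)] = 0.0
        out[cat] = d
    return out


def query(
    index: RetrievalIndex,
    q: FeatureVector | dict | pd.Series,
    k: int = 5,
    exclude_self: bool = False,
    mode: str = "mean",
) -> RetrievalResult:
    """Retrieve the top-k most similar database scans for a query scan.

    ``mode='mean'`` ranks by the unweighted mean of the four per-category
    cosine distances; ``mode='concat'`` ranks by the cosine distance between
    the full concatenated normalized vectors (per-category distances are
    still reported).  Ties are broken by scan_id; with ``exclude_self`` the
    database entry with the query's own scan_id is dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("mean", "concat"):
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(q, FeatureVector):
        scan_id = q["scan_id"] if "scan_id" in q else "query"
        q = FeatureVector.from_mapping(str(scan_id), q)

    u = q.values / index.normalizers
    per_cat = _category_distances(u, index.normalized)
    if mode == "mean":
        combined = np.mean([per_cat[c] for c in CATEGORY_NAMES], axis=0)
    else:
        combined = _concat_distance(u, index.normalized)

    order = sorted(
        range(len(index)),
        key=lambda i: (combined[i], index.scan_ids[i]),
    )
    ranked = []
    for i in order:
        sid = index.scan_ids[i]
        if exclude_self and sid == q.scan_id:
            continue
        ranked.append(
            (sid, float(combined[i]), {c: float(per_cat[c][i]) for c in CATEGORY_NAMES})
        )
        if len(ranked) == k:
            break
    return RetrievalResult(q.scan_id, ranked)


def _concat_distance(u: np.ndarray, entries: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(entries, axis=1)
    d = np.ones(len(entries))
    both = (nu > 0) & (nv > 0)
    if nu > 0:
        d[both] = 1.0 - np.clip((entries[both] @ u) / (nv[both] * nu), -1.0, 1.0)
    d[(nu == 0) & (nv == 0)] = 0.0
    return d


_SCHEMA = "lungcbir-index"


def save_index(index: RetrievalIndex, path: str | os.PathLike) -> None:
    """Serialize the index as JSON (floats round-trip bit-exact)."""
    payload = {
        "format": _SCHEMA,
        "version": 1,
        "feature_names": list(index.feature_names),
        "scan_ids": list(index.scan_ids),
        "normalizers": index.normalizers.tolist(),
        "normalized": index.normalized.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_index(path: str | os.PathLike) -> RetrievalIndex:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexFormatError(f"not a valid index file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _SCHEMA:
        raise IndexFormatError("missing or wrong 'format' marker")
    try:
        index = RetrievalIndex(
            scan_ids=list(payload["scan_ids"]),
            normalized=np.asarray(payload["normalized"], dtype=float),
            normalizers=np.asarray(payload["normalizers"], dtype=float),
            feature_names=tuple(payload["feature_names"]),
        )
    except KeyError as exc:
        raise IndexFormatError(f"missing field {exc}") from exc
    if index.normalized.shape != (len(index.scan_ids), len(index.feature_names)):
        raise IndexFormatError("shape mismatch between scan_ids and matrix")
    return index
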