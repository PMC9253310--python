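"""Seed-unit x target structural-connectivity feature matrices.

A *fingerprint* is the per-seed-unit vector of connection strengths to a
fixed, ordered set of target regions. This module builds fingerprint
matrices from streamline endpoint tables, normalizes them for clustering,
and implements the label-constrained seed dilation used to absorb the
ambiguous seed/neighbor boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "SeedRegion",
    "Fingerprint",
    "dilate_seed_region",
    "build_fingerprint_matrix",
    "normalize_fingerprints",
    "fingerprint_to_endpoint_table",
]

#: Recognized normalization tags for Fingerprint matrices.
NORMALIZATIONS = ("raw", "row_proportion", "log1p")


@dataclass(frozen=True)
class SeedRegion:
    """A set of seed units (voxels or vertices) with mm coordinates."""

    coordinates: np.ndarray  # (n, 3) float, mm
    unit_ids: np.ndarray  # (n,) unique identifiers
    hemisphere: str = "left"

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        ids = np.asarray(self.unit_ids)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if coords.shape[0] == 0:
            raise ValueError("empty seed region")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if ids.shape[0] != coords.shape[0]:
            raise ValueError("unit_ids must match coordinates")
        if len(set(ids.tolist())) != len(ids):
            raise ValueError("unit_ids must be unique")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "unit_ids", ids)

    @property
    def n_units(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Fingerprint:
    """Non-negative seed-unit x target connectivity matrix.

    ``zero_rows`` flags units with no streamlines at all; such rows are
    left untouched by row-proportion normalization and excluded from
    profile averaging.
    """

    matrix: np.ndarray  # (n_units, n_targets) >= 0
    target_names: tuple
    normalization: str = "raw"
    zero_rows: np.ndarray = field(default=None)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("matrix entries must be finite and >= 0")
        if len(self.target_names) != m.shape[1]:
            raise ValueError("target_names must match matrix columns")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.matrix = m
        self.target_names = tuple(self.target_names)
        if self.zero_rows is None:
            self.zero_rows = m.sum(axis=1) == 0
        else:
            self.zero_rows = np.asarray(self.zero_rows, dtype=bool)
        if self.normalization == "row_proportion":
            sums = m[~self.zero_rows].sum(axis=1)
            if sums.size and not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("row_proportion rows must sum to 1")

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_targets(self) -> int:
        return self.matrix.shape[1]


def dilate_seed_region(
    seed: SeedRegion,
    neighbor_coordinates: np.ndarray,
    neighbor_labels: np.ndarray,
    radius_mm: float = 2.1,
    allowed_regions=("STG", "IN"),
) -> SeedRegion:
    """Extend a seed region into specific neighboring regions.

    An off-seed unit is admitted iff its region label is in
    ``allowed_regions`` and its Euclidean distance to the nearest original
    seed unit is <= ``radius_mm``. The directional constraint of the
    dilation is expressed through the allowed label set; original seed
    units are always retained.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    allowed = set(allowed_regions)
    if not allowed:
        raise ValueError("allowed_regions must be non-empty")
    coords = np.asarray(neighbor_coordinates, dtype=float).reshape(-1, 3)
    labels = np.asarray(neighbor_labels)
    if coords.shape[0] != labels.shape[0]:
        raise ValueError("neighbor coordinates/labels length mismatch")

    in_allowed = np.isin(labels, sorted(allowed))
    keep = np.zeros(coords.shape[0], dtype=bool)
    if in_allowed.any():
        d = cdist(coords[in_allowed], seed.coordinates).min(axis=1)
        keep[np.flatnonzero(in_allowed)[d <= radius_mm]] = True

    if not keep.any():
        return seed
    new_coords = np.vstack([seed.coordinates, coords[keep]])
    # dilated units get ids disjoint from the originals
    extra_ids = np.array([f"dil_{i}" for i in np.flatnonzero(keep)], dtype=object)
    new_ids = np.concatenate([np.asarray(seed.unit_ids, dtype=object), extra_ids])
    return SeedRegion(new_coords, new_ids, seed.hemisphere)


ENDPOINT_COLUMNS = ("seed_unit_id", "target", "count")


def build_fingerprint_matrix(
    endpoints: pd.DataFrame, seed: SeedRegion, target_names
) -> Fingerprint:
    """Aggregate a streamline endpoint table into a raw count matrix.

    ``endpoints`` must have columns ``seed_unit_id``, ``target``, ``count``
    with positive integer counts and unique (unit, target) pairs. Units
    absent from the table produce all-zero rows, which are flagged.
    """
    target_names = tuple(target_names)
    if not set(ENDPOINT_COLUMNS) <= set(endpoints.columns):
        raise ValueError(f"endpoint table needs columns {ENDPOINT_COLUMNS}")
    n = seed.n_units
    matrix = np.zeros((n, len(target_names)), dtype=float)
    if len(endpoints):
        counts = endpoints["count"].to_numpy()
        if np.any(counts <= 0) or np.any(counts != np.floor(counts)):
            raise ValueError("counts must be positive integers")
        if endpoints.duplicated(subset=["seed_unit_id", "target"]).any():
            raise ValueError("duplicate (seed_unit_id, target) records")
        unknown = set(endpoints["target"]) - set(target_names)
        if unknown:
            raise ValueError(f"unknown target labels: {sorted(unknown)}")
        unit_index = {u: i for i, u in enumerate(seed.unit_ids)}
        missing = set(endpoints["seed_unit_id"]) - set(unit_index)
        if missing:
            raise ValueError(f"records for units outside seed region: {sorted(map(str, missing))[:5]}")
        t_index = {t: j for j, t in enumerate(target_names)}
        rows = endpoints["seed_unit_id"].map(unit_index).to_numpy()
        cols = endpoints["target"].map(t_index).to_numpy()
        np.add.at(matrix, (rows, cols), counts.astype(float))
    fp = Fingerprint(matrix, target_names, "raw")
    if fp.zero_rows.any():
        warnings.warn(
            f"{int(fp.zero_rows.sum())} seed unit(s) have zero streamline counts",
            stacklevel=2,
        )
    return fp


def normalize_fingerprints(fp: Fingerprint, method: str = "row_proportion") -> Fingerprint:
    """Return a normalized copy of a raw fingerprint matrix.

    ``row_proportion`` divides each non-flagged row by its sum (flagged
    all-zero rows stay zero); ``log1p`` applies log(1 + x) elementwise;
    ``raw`` is the identity.
    """
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}")
    if fp.normalization != "raw":
        raise ValueError("can only normalize a raw fingerprint")
    if method == "raw":
        return replace(fp, matrix=fp.matrix.copy())
    if method == "row_proportion":
        sums = fp.matrix.sum(axis=1, keepdims=True)
        safe = np.where(sums == 0, 1.0, sums)
        return Fingerprint(fp.matrix / safe, fp.target_names, "row_proportion", fp.zero_rows)
    return Fingerprint(np.log1p(fp.matrix), fp.target_names, "log1p", fp.zero_rows)


def fingerprint_to_endpoint_table(fp: Fingerprint, unit_ids) -> pd.DataFrame:
    """Flatten a raw integer fingerprint into an endpoint table (inverse of
    :func:`build_fingerprint_matrix` for integer matrices)."""
    if fp.normalization != "raw":
        raise ValueError("endpoint tables only make sense for raw counts")
    unit_ids = np.asarray(unit_ids)
    if unit_ids.shape[0] != fp.n_units:
        raise ValueError("unit_ids must match fingerprint rows")
    rows, cols = np.nonzero(fp.matrix)
    return pd.DataFrame(
        {
            "seed_unit_id": unit_ids[rows],
            "target": [fp.target_names[c] for c in cols],
            "count": fp.matrix[rows, cols].astype(int),
        }
    )
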