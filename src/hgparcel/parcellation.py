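"""Cluster connectivity fingerprints into subregions.

K-means (Lloyd, k-means++ init, best-of-restarts) over a sweep of K,
elbow selection on the inertia profile with the Kneedle rule for a
decreasing convex curve, and canonical relabeling of the clusters along
the region's anatomical axis (HG2 = lowest-axis band, HG1 = middle,
HG3 = highest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .fingerprints import Fingerprint

__all__ = [
    "InertiaProfile",
    "ParcellationResult",
    "cluster_fingerprints",
    "inertia_profile",
    "select_k_kneedle",
    "group_select_k",
    "canonicalize_labels",
    "parcellate_subject",
    "NoElbowError",
]

CANONICAL_ORDER = ("HG1", "HG2", "HG3")


class NoElbowError(ValueError):
    """Raised when an inertia profile has no detectable knee."""


@dataclass(frozen=True)
class InertiaProfile:
    """K-means objective (sum of squared distances to nearest center) per K."""

    k_values: np.ndarray
    inertia: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.k_values, dtype=int)
        inert = np.asarray(self.inertia, dtype=float)
        if k.shape != inert.shape or k.ndim != 1:
            raise ValueError("k_values and inertia must be matching 1-D arrays")
        if np.any(np.diff(k) <= 0):
            raise ValueError("k_values must be strictly increasing")
        if np.any(inert < 0):
            raise ValueError("inertia must be non-negative")
        object.__setattr__(self, "k_values", k)
        object.__setattr__(self, "inertia", inert)


@dataclass
class ParcellationResult:
    labels: np.ndarray  # canonical string labels per seed unit
    chosen_k: int
    inertia_profile: InertiaProfile
    rng_seed: int
    n_restarts: int


def _feature_matrix(fp) -> np.ndarray:
    if isinstance(fp, Fingerprint):
        return fp.matrix
    return np.asarray(fp, dtype=float)


def cluster_fingerprints(fp, k: int, rng_seed: int = 0, n_restarts: int = 10):
    """Run k-means at a fixed K; return (integer labels, inertia).

    Best inertia over ``n_restarts`` k-means++ initializations,
    deterministic given ``rng_seed``.
    """
    X = _feature_matrix(fp)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed).fit(X)
    if len(np.unique(km.labels_)) < k:
        raise RuntimeError("k-means converged with an empty cluster")
    return km.labels_, float(km.inertia_)


def inertia_profile(
    fp, k_min: int = 2, k_max: int = 10, rng_seed: int = 0, n_restarts: int = 10
) -> InertiaProfile:
    """Sweep K over [k_min, k_max] and collect the inertia per K.

    With finite restarts the curve can be locally non-monotone; any
    violating K is re-run once with doubled restarts, then accepted as-is
    with a warning.
    """
    X = _feature_matrix(fp)
    if k_max > X.shape[0]:
        raise ValueError("k_max exceeds number of seed units")
    if k_min < 2 or k_min > k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k_max:
        # duplicate feature rows bound the number of non-empty clusters
        warnings.warn(
            f"only {n_distinct} distinct rows; capping k_max at {n_distinct}",
            stacklevel=2,
        )
        k_max = n_distinct
        if k_min > k_max:
            raise ValueError("fewer distinct rows than k_min clusters")
    ks = np.arange(k_min, k_max + 1)
    inert = np.array([cluster_fingerprints(X, k, rng_seed, n_restarts)[1] for k in ks])
    for i in range(1, len(ks)):
        if inert[i] > inert[i - 1]:
            _, redo = cluster_fingerprints(X, int(ks[i]), rng_seed, 2 * n_restarts)
            inert[i] = min(inert[i], redo)
            if inert[i] > inert[i - 1]:
                warnings.warn(
                    f"inertia profile non-monotone at k={ks[i]} after retry",
                    stacklevel=2,
                )
    return InertiaProfile(ks, inert)


def select_k_kneedle(profile: InertiaProfile, sensitivity: float = 1.0) -> int:
    """Kneedle knee detection for a decreasing (convex) inertia curve.

    Min-max normalize both axes, form the difference curve
    ``d = (1 - y_n) - x_n`` and return the K at the first local maximum of
    ``d`` exceeding ``sensitivity * mean(diff(x_n))``. A flat/linear
    profile (no qualifying maximum) raises :class:`NoElbowError` rather
    than silently defaulting.
    """
    k = profile.k_values
    y = profile.inertia
    if len(k) < 3:
        raise ValueError("need at least 3 points to detect an elbow")
    y_span = y.max() - y.min()
    if y_span == 0:
        raise NoElbowError("constant inertia profile has no elbow")
    xn = (k - k.min()) / (k.max() - k.min())
    yn = (y - y.min()) / y_span
    d = (1.0 - yn) - xn
    threshold = sensitivity * float(np.mean(np.diff(xn)))
    for i in range(1, len(d) - 1):
        if d[i] >= d[i - 1] and d[i] >= d[i + 1] and d[i] > threshold:
            return int(k[i])
    raise NoElbowError("no local maximum of the difference curve exceeds threshold")


def group_select_k(profiles, sensitivity: float = 1.0) -> int:
    """Group-level K: average min-max-normalized inertia profiles across
    subjects (shared K grid required) and apply Kneedle once."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    k0 = profiles[0].k_values
    norm = []
    for p in profiles:
        if not np.array_equal(p.k_values, k0):
            raise ValueError("profiles must share the same K grid")
        span = p.inertia.max() - p.inertia.min()
        if span == 0:
            raise NoElbowError("constant inertia profile in group")
        norm.append((p.inertia - p.inertia.min()) / span)
    mean_profile = InertiaProfile(k0, np.mean(norm, axis=0))
    return select_k_kneedle(mean_profile, sensitivity)


def canonicalize_labels(raw_labels, axis_coordinate) -> np.ndarray:
    """Map arbitrary integer cluster labels to anatomical names.

    For 3 clusters: smallest mean axis coordinate -> HG2, largest -> HG3,
    remaining -> HG1 (axis-mean ties resolved so the larger cluster takes
    the central HG1 slot). For any other K, clusters are named
    ``HG_a1..HG_ak`` in ascending axis-centroid order.
    """
    raw = np.asarray(raw_labels)
    axis = np.asarray(axis_coordinate, dtype=float)
    if raw.shape != axis.shape:
        raise ValueError("labels and axis coordinates must align")
    if np.any(~np.isfinite(axis)):
        raise ValueError("axis coordinates must be finite")
    clusters = np.unique(raw)
    means = {c: axis[raw == c].mean() for c in clusters}
    sizes = {c: int((raw == c).sum()) for c in clusters}
    # ascending axis mean; on ties the smaller cluster goes to the extreme
    order = sorted(clusters, key=lambda c: (means[c], sizes[c]))
    if len(clusters) == 3:
        name_of = {order[0]: "HG2", order[1]: "HG1", order[2]: "HG3"}
    else:
        name_of = {c: f"HG_a{i + 1}" for i, c in enumerate(order)}
    return np.array([name_of[c] for c in raw])


def parcellate_subject(
    fp,
    axis_coordinate,
    k_min: int = 2,
    k_max: int = 10,
    rng_seed: int = 0,
    n_restarts: int = 10,
    sensitivity: float = 1.0,
    k_override: int | None = None,
) -> ParcellationResult:
    """Full per-subject parcellation: sweep -> Kneedle -> cluster -> canonicalize.

    ``k_override`` bypasses elbow selection (used for group-level K). An
    exactly-zero inertia inside the sweep (perfectly separable data, e.g.
    a noise-free phantom) is an unambiguous elbow and short-circuits the
    Kneedle rule.
    """
    profile = inertia_profile(fp, k_min, k_max, rng_seed, n_restarts)
    if k_override is not None:
        k = int(k_override)
    else:
        zero = profile.inertia <= 1e-12 * max(1.0, profile.inertia[0])
        if zero.any():
            k = int(profile.k_values[np.argmax(zero)])
        else:
            k = select_k_kneedle(profile, sensitivity)
    raw, _ = cluster_fingerprints(fp, k, rng_seed, n_restarts)
    labels = canonicalize_labels(raw, axis_coordinate)
    return ParcellationResult(labels, k, profile, rng_seed, n_restarts)
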