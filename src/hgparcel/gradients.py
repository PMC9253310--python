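"""Seed-based functional gradient mapping within the seed region.

Pipeline per subject: z-normalize time series, SVD-compress the
outside-seed vertex x time matrix into singular-value-weighted component
time courses, correlate seed vertices against the components, build a
cosine-similarity affinity over seed vertices, and PCA the affinity into
low-dimensional "gradients". Subjects are aligned onto a group reference
(PCA of the stacked subject gradients) by orthogonal Procrustes without
scaling.

The singular-value weighting of the components keeps the seed-to-outside
inner-product geometry intact, so at full rank the component-space
affinity equals the affinity computed directly from seed-to-vertex
correlation fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "TimeSeriesBundle",
    "GradientResult",
    "znormalize_timeseries",
    "svd_reduce",
    "connectivity_affinity",
    "pca_gradients",
    "subject_gradient",
    "build_reference_gradient",
    "procrustes_align",
    "stratify_gradient",
]


@dataclass
class TimeSeriesBundle:
    """Seed-vertex and outside-vertex time series plus target ROI structure.

    ``target_membership`` assigns each outside vertex to a target ROI;
    ``target_mean_series`` holds the per-ROI mean series (rows follow
    ``target_names``).
    """

    seed_matrix: np.ndarray  # (n_seed, T)
    outside_matrix: np.ndarray  # (n_outside, T)
    target_membership: np.ndarray  # (n_outside,) target name per outside vertex
    target_names: tuple
    target_mean_series: np.ndarray = None  # (n_targets, T)
    association_targets: tuple = ()

    def __post_init__(self):
        seed = np.atleast_2d(np.asarray(self.seed_matrix, dtype=float))
        out = np.atleast_2d(np.asarray(self.outside_matrix, dtype=float))
        if seed.shape[1] != out.shape[1]:
            raise ValueError("seed and outside matrices must share time length")
        if not (np.all(np.isfinite(seed)) and np.all(np.isfinite(out))):
            raise ValueError("time series must be finite")
        membership = np.asarray(self.target_membership)
        if membership.shape[0] != out.shape[0]:
            raise ValueError("target_membership must match outside vertices")
        self.seed_matrix = seed
        self.outside_matrix = out
        self.target_membership = membership
        self.target_names = tuple(self.target_names)
        if self.target_mean_series is None:
            means = np.full((len(self.target_names), seed.shape[1]), np.nan)
            for i, name in enumerate(self.target_names):
                mask = membership == name
                if mask.any():
                    means[i] = out[mask].mean(axis=0)
            self.target_mean_series = means
        else:
            self.target_mean_series = np.asarray(self.target_mean_series, dtype=float)

    @property
    def n_timepoints(self) -> int:
        return self.seed_matrix.shape[1]


@dataclass
class GradientResult:
    gradients: np.ndarray  # (n_seed_vertices, n_components)
    variance_explained: np.ndarray  # per-component fraction, non-increasing

    def __post_init__(self):
        g = np.asarray(self.gradients, dtype=float)
        v = np.asarray(self.variance_explained, dtype=float)
        if g.ndim != 2 or v.ndim != 1 or v.shape[0] != g.shape[1]:
            raise ValueError("gradients (n, k) must match variance_explained (k,)")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")
        if v.sum() > 1 + 1e-9 or np.any(v < -1e-12):
            raise ValueError("variance_explained fractions must lie in [0, 1]")
        self.gradients = g
        self.variance_explained = v


def znormalize_timeseries(matrix: np.ndarray) -> np.ndarray:
    """Row-wise z-normalization (mean 0, population SD 1).

    Constant rows cannot be normalized; they are dropped with a warning.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if x.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    sd = x.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} zero-variance series", stacklevel=2)
        x = x[~bad]
        sd = sd[~bad]
    if x.shape[0] == 0:
        raise ValueError("all series have zero variance")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def svd_reduce(outside_matrix: np.ndarray, n_components="full") -> np.ndarray:
    """Compress an outside-vertex x time matrix to component time courses.

    Returns the singular-value-weighted right singular vectors
    (rows of S @ Vt), top ``n_components`` by singular value; ``"full"``
    keeps the numerical rank. The weighting preserves the Gram matrix of
    any projection against the row space.
    """
    x = np.atleast_2d(np.asarray(outside_matrix, dtype=float))
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if n_components == "full":
        k = rank
    else:
        k = int(n_components)
        if k <= 0:
            raise ValueError("n_components must be positive")
        if k > rank:
            raise ValueError(f"n_components={k} exceeds rank {rank}")
    return s[:k, None] * vt[:k]


def connectivity_affinity(seed_matrix: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Cosine-similarity affinity between seed-vertex connectivity fingerprints.

    Each seed vertex's fingerprint is its vector of (singular-value-
    weighted) correlations with the component time courses: the z-scored
    seed series projected onto the component rows and scaled by 1/T. The
    affinity is the pairwise cosine similarity of those fingerprints.
    """
    seed = np.atleast_2d(np.asarray(seed_matrix, dtype=float))
    comp = np.atleast_2d(np.asarray(components, dtype=float))
    if seed.shape[1] != comp.shape[1]:
        raise ValueError("seed and components must share time length")
    zs = znormalize_timeseries(seed)
    fingerprints = zs @ comp.T / seed.shape[1]
    norms = np.linalg.norm(fingerprints, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm connectivity fingerprint")
    fn = fingerprints / norms[:, None]
    aff = np.clip(fn @ fn.T, -1.0, 1.0)
    aff = (aff + aff.T) / 2.0
    np.fill_diagonal(aff, 1.0)
    return aff


def pca_gradients(affinity: np.ndarray, n_gradients: int = 3) -> GradientResult:
    """PCA of the (column-centered) affinity matrix.

    Rows are observations; gradients are the projections onto the top
    principal axes, with variance-explained fractions from the squared
    singular values of the centered matrix.
    """
    a = np.asarray(affinity, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("affinity must be square")
    if not 1 <= n_gradients < n:
        raise ValueError("need 1 <= n_gradients < matrix size")
    centered = a - a.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("degenerate (constant) affinity matrix")
    scores = u[:, :n_gradients] * s[:n_gradients]
    frac = (s[:n_gradients] ** 2) / total
    return GradientResult(scores, frac)


def subject_gradient(ts_bundle: TimeSeriesBundle, n_gradients: int = 3,
                     n_components="full") -> GradientResult:
    """Compose the per-subject gradient pipeline from a time-series bundle."""
    z_out = znormalize_timeseries(ts_bundle.outside_matrix)
    comps = svd_reduce(z_out, n_components)
    aff = connectivity_affinity(ts_bundle.seed_matrix, comps)
    return pca_gradients(aff, n_gradients)


def build_reference_gradient(subject_gradients) -> np.ndarray:
    """Group reference: PCA of subjects' gradients stacked along components.

    All subjects must share the seed mesh (same vertex count). Returns an
    (n_vertices, k) reference with k = per-subject component count.
    """
    mats = [np.asarray(g.gradients if isinstance(g, GradientResult) else g, dtype=float)
            for g in subject_gradients]
    if not mats:
        raise ValueError("no subject gradients given")
    n, k = mats[0].shape
    for m in mats:
        if m.shape[0] != n:
            raise ValueError("subjects must share the number of seed vertices")
    stack = np.hstack(mats)
    centered = stack - stack.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, :k] * s[:k]


def procrustes_align(subject_gradients, reference) -> np.ndarray:
    """Align a subject's gradients onto the reference by an orthogonal map.

    Columns of both matrices are centered; the rotation/reflection
    minimizing the Frobenius distance is applied. No scaling, so gradient
    magnitudes remain comparable across subregions.
    """
    g = np.asarray(
        subject_gradients.gradients
        if isinstance(subject_gradients, GradientResult)
        else subject_gradients,
        dtype=float,
    )
    ref = np.asarray(reference, dtype=float)
    if g.shape != ref.shape:
        raise ValueError("subject and reference gradients must share shape")
    gc = g - g.mean(axis=0, keepdims=True)
    rc = ref - ref.mean(axis=0, keepdims=True)
    if not np.any(gc):
        raise ValueError("degenerate (zero) gradient matrix")
    rotation, _ = orthogonal_procrustes(gc, rc)
    return gc @ rotation


def stratify_gradient(aligned_gradients, labels, low="HG2", high="HG3") -> dict:
    """Mean first-gradient value per subregion.

    The gradient's sign is arbitrary; orientation is fixed so that the
    ``high`` subregion mean exceeds the ``low`` one.
    """
    g = np.asarray(aligned_gradients, dtype=float)
    g1 = g[:, 0] if g.ndim == 2 else g
    labels = np.asarray(labels)
    names = sorted(np.unique(labels).tolist())
    if low not in names or high not in names:
        raise ValueError(f"labels must include {low} and {high}")
    means = {}
    for name in names:
        mask = labels == name
        if not mask.any():
            raise ValueError(f"empty subregion {name}")
        means[name] = float(g1[mask].mean())
    if means[high] < means[low]:
        means = {k: -v for k, v in means.items()}
    return means
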