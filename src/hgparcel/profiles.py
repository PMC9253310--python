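"""Per-subregion structural/functional/morphometric profiles and
cross-subject paired contrasts with FDR control.

Functional connectivity is Pearson correlation between each seed unit's
time series and each target ROI's mean time series, passed through the
scale-free soft threshold ((r + 1) / 2) ** beta (beta = 6 by default)
*before* averaging within a subregion, then averaged per subregion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SoftThresholdParams",
    "MorphometryMaps",
    "soft_threshold",
    "inverse_soft_threshold",
    "functional_connectivity_profile",
    "structural_connectivity_profile",
    "morphometry_profile",
    "paired_ttest",
    "fdr_bh",
    "compare_subregions",
]


@dataclass(frozen=True)
class SoftThresholdParams:
    """Scale-free soft-threshold exponent."""

    beta: float = 6.0

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclass
class MorphometryMaps:
    """Per-unit myelin proxy (T1w/T2w ratio, unitless) and thickness (mm)."""

    myelin: np.ndarray
    thickness: np.ndarray

    def __post_init__(self):
        my = np.asarray(self.myelin, dtype=float)
        th = np.asarray(self.thickness, dtype=float)
        if my.shape != th.shape or my.ndim != 1:
            raise ValueError("myelin and thickness must be matching 1-D arrays")
        if not (np.all(np.isfinite(my)) and np.all(np.isfinite(th))):
            raise ValueError("morphometry maps must be finite")
        if np.any(th <= 0):
            raise ValueError("thickness must be positive")
        self.myelin = my
        self.thickness = th


def soft_threshold(r, beta: float = 6.0):
    """Map a correlation in [-1, 1] to [0, 1] via ((r + 1) / 2) ** beta.

    Strictly increasing for beta > 0; vectorized over ``r``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    out = ((np.clip(arr, -1.0, 1.0) + 1.0) / 2.0) ** beta
    return float(out) if np.isscalar(r) else out


def inverse_soft_threshold(w, beta: float = 6.0):
    """Inverse of :func:`soft_threshold` on [0, 1]."""
    arr = np.asarray(w, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("soft-thresholded weights must lie in [0, 1]")
    out = 2.0 * np.clip(arr, 0.0, 1.0) ** (1.0 / beta) - 1.0
    return float(out) if np.isscalar(w) else out


def _subregion_names(labels) -> list:
    return sorted(np.unique(np.asarray(labels)).tolist())


def _row_standardize(x: np.ndarray):
    """Z-score rows; rows with zero variance come back as NaN rows."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, np.nan)
    return z, (sd.ravel() == 0)


def functional_connectivity_profile(ts_bundle, labels, params: SoftThresholdParams | None = None):
    """Subregion x target matrix of soft-thresholded seed-to-ROI correlations.

    Per seed unit and target ROI mean series, compute Pearson r, apply the
    soft threshold per pair, then average within each subregion.
    Zero-variance series are excluded with a warning.
    """
    params = params or SoftThresholdParams()
    seed = np.asarray(ts_bundle.seed_matrix, dtype=float)
    targets = np.asarray(ts_bundle.target_mean_series, dtype=float)
    names = _subregion_names(labels)
    labels = np.asarray(labels)
    if seed.shape[1] != targets.shape[1]:
        raise ValueError("seed and target series must share time length")
    T = seed.shape[1]
    if T < 10:
        raise ValueError("need at least 10 timepoints")
    zs, bad_seed = _row_standardize(seed)
    zt, bad_t = _row_standardize(targets)
    if bad_seed.any() or bad_t.any():
        warnings.warn(
            f"excluding {int(bad_seed.sum())} seed and {int(bad_t.sum())} target "
            "zero-variance series from FC",
            stacklevel=2,
        )
    r = np.clip(zs @ zt.T / T, -1.0, 1.0)  # (n_seed, n_targets), NaN where excluded
    w = np.where(np.isnan(r), np.nan, soft_threshold(np.nan_to_num(r), params.beta))
    out = np.empty((len(names), targets.shape[0]))
    for i, name in enumerate(names):
        block = w[labels == name]
        if block.size == 0:
            raise ValueError(f"empty subregion {name}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[i] = np.nanmean(block, axis=0)
    return pd.DataFrame(out, index=names, columns=list(ts_bundle.target_names))


def structural_connectivity_profile(fp, labels):
    """Subregion x target matrix of mean row-proportion fingerprints.

    Per-unit proportions are averaged so the profile is independent of
    subregion size; flagged all-zero rows are excluded.
    """
    from .fingerprints import Fingerprint, normalize_fingerprints

    if not isinstance(fp, Fingerprint):
        raise TypeError("fp must be a Fingerprint")
    if fp.normalization == "raw":
        fp = normalize_fingerprints(fp, "row_proportion")
    elif fp.normalization != "row_proportion":
        raise ValueError("structural profiles need raw or row_proportion fingerprints")
    labels = np.asarray(labels)
    names = _subregion_names(labels)
    out = np.empty((len(names), fp.n_targets))
    for i, name in enumerate(names):
        mask = (labels == name) & ~fp.zero_rows
        if not mask.any():
            raise ValueError(f"empty subregion {name}")
        out[i] = fp.matrix[mask].mean(axis=0)
    return pd.DataFrame(out, index=names, columns=list(fp.target_names))


def morphometry_profile(maps: MorphometryMaps, labels):
    """Per-subregion mean myelin and thickness."""
    labels = np.asarray(labels)
    names = _subregion_names(labels)
    rows = []
    for name in names:
        mask = labels == name
        if not mask.any():
            raise ValueError(f"empty subregion {name}")
        rows.append([maps.myelin[mask].mean(), maps.thickness[mask].mean()])
    return pd.DataFrame(rows, index=names, columns=["myelin", "thickness"])


def paired_ttest(x, y):
    """Two-sided paired t-test; returns (t, p) with n - 1 df.

    Requires n >= 3. Identical inputs give (0, 1); zero-variance nonzero
    differences are degenerate and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("paired t-test requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: degenerate t-test")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini–Hochberg step-up FDR.

    Returns (adjusted p-values, rejection flags) in input order; adjusted
    p_(i) = min_{j >= i} m * p_(j) / j capped at 1, rejected iff <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


def compare_subregions(family_values: dict, q: float = 0.05) -> pd.DataFrame:
    """Paired contrasts between every subregion pair, FDR within family.

    ``family_values`` maps a family name (e.g. ``"fc"``, ``"myelin"``) to
    either an (n_subjects, n_subregions) array or an
    (n_subjects, n_subregions, n_targets) array paired with target names:
    ``{"fc": (values, target_names), "myelin": values, ...}``.
    Subregions are taken in sorted canonical order. BH correction is
    applied separately within each family.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    frames = []
    for family, payload in family_values.items():
        if isinstance(payload, tuple):
            values, target_names = payload
        else:
            values, target_names = payload, None
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:
            values = values[:, :, None]
            target_names = [family]
        elif values.ndim != 3:
            raise ValueError(f"family {family!r}: values must be 2-D or 3-D")
        n_subj, n_sub, n_targ = values.shape
        if n_subj < 3:
            raise ValueError("need at least 3 subjects")
        if target_names is None or len(target_names) != n_targ:
            raise ValueError(f"family {family!r}: target names must match last axis")
        sub_names = [f"sub{i}" for i in range(n_sub)]
        rows = []
        for (i, a), (j, b) in itertools.combinations(enumerate(sub_names), 2):
            for t_idx, t_name in enumerate(target_names):
                t_stat, p = paired_ttest(values[:, i, t_idx], values[:, j, t_idx])
                rows.append((family, f"{a}>{b}", t_name, t_stat, p))
        fam = pd.DataFrame(rows, columns=["family", "pair", "target", "t", "p"])
        adj, rej = fdr_bh(fam["p"].to_numpy(), q)
        fam["p_adjusted"] = adj
        fam["significant"] = rej
        frames.append(fam)
    return pd.concat(frames, ignore_index=True)


def compare_cohort_profiles(
    sc=None, fc=None, myelin=None, thickness=None, gradient_means=None,
    subregion_names=("HG1", "HG2", "HG3"), target_names=None, q: float = 0.05,
) -> pd.DataFrame:
    """Convenience wrapper: assemble named families from cohort-level stacks
    (n_subjects x n_subregions [x n_targets]) and run :func:`compare_subregions`
    with subregion names substituted into the pair labels."""
    families = {}
    if sc is not None:
        families["sc"] = (np.asarray(sc), list(target_names))
    if fc is not None:
        families["fc"] = (np.asarray(fc), list(target_names))
    if myelin is not None:
        families["myelin"] = np.asarray(myelin)
    if thickness is not None:
        families["thickness"] = np.asarray(thickness)
    if gradient_means is not None:
        families["gradient"] = np.asarray(gradient_means)
    table = compare_subregions(families, q)
    rename = {f"sub{i}": name for i, name in enumerate(subregion_names)}
    table["pair"] = table["pair"].map(
        lambda s: ">".join(rename.get(part, part) for part in s.split(">"))
    )
    return table
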