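"""Synthetic multi-subject cohorts with the statistical structure the
analysis pipeline assumes.

The phantom is a lattice-embedded elongated seed region with three
planted subregions ordered along an anatomical axis (HG2 at the
medial-posterior-superior pole, HG1 central, HG3 at the lateral-
anterior-inferior pole). Fingerprints are multinomial streamline-count
draws from band-specific target profiles (HG3 biased toward STG, HG2
toward insula/SMG/SPG, HG1 intermediate). Time series mix two latent
network signals with a mixing weight equal to the axis coordinate, which
plants a recoverable medial-to-lateral connectivity gradient. This is an
emulation of the statistics the method consumes, not a model of BOLD
physiology or fiber geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fingerprints import Fingerprint, SeedRegion
from .gradients import TimeSeriesBundle
from .profiles import MorphometryMaps

__all__ = [
    "DEFAULT_TARGETS",
    "ASSOCIATION_TARGETS",
    "PhantomConfig",
    "Phantom",
    "SubjectBundle",
    "Cohort",
    "make_phantom",
    "band_base_profiles",
    "simulate_fingerprints",
    "simulate_timeseries",
    "simulate_morphometry",
    "make_cohort",
]

# 42 intrahemispheric target regions: 33 cortical labels (seed region
# itself excluded; STG/SMG/SPG/IN short names for the featured targets)
# plus 9 subcortical/cerebellar labels.
DEFAULT_TARGETS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "IN", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "SPG", "STG", "SMG", "temporalpole", "thalamus", "caudate", "putamen",
    "pallidum", "hippocampus", "amygdala", "accumbens", "cerebellum",
    "ventraldc",
)

#: Targets driven by the association/paralimbic latent signal (network B);
#: the remainder follow the sensorimotor-like latent (network A).
ASSOCIATION_TARGETS = frozenset(
    {
        "IN", "STG", "precuneus", "posteriorcingulate", "isthmuscingulate",
        "rostralanteriorcingulate", "caudalanteriorcingulate", "amygdala",
        "hippocampus", "parahippocampal", "cerebellum", "entorhinal",
        "temporalpole", "middletemporal", "inferiortemporal", "fusiform",
        "bankssts", "medialorbitofrontal", "lateralorbitofrontal",
        "frontalpole", "accumbens",
    }
)

BAND_NAMES = ("HG1", "HG2", "HG3")
#: Band order along the anatomical axis (low -> high axis coordinate).
AXIS_BAND_ORDER = ("HG2", "HG1", "HG3")


@dataclass(frozen=True)
class PhantomConfig:
    """All generation parameters for one synthetic subject/cohort."""

    n_seed_units: int = 300
    hemisphere: str = "left"
    #: fractions for (HG1, HG2, HG3); must sum to 1, all positive
    band_proportions: tuple = (0.46, 0.24, 0.30)
    target_names: tuple = DEFAULT_TARGETS
    n_outside_vertices: int = 500
    n_timepoints: int = 1400
    n_streamlines_per_unit: int = 10000
    #: Dirichlet concentration for per-unit fingerprint perturbation
    #: (np.inf = no perturbation)
    fingerprint_concentration: float = 1000.0
    #: draw multinomial streamline counts; False = exact expected counts
    sample_streamlines: bool = True
    timeseries_noise_sd: float = 1.0
    outside_noise_sd: float = 0.5
    myelin_sd: float = 0.08
    thickness_sd: float = 0.12
    #: per-subject Gaussian jitter of the two band cut points, as a
    #: fraction of the axis (units of axis_coordinate)
    boundary_jitter_sd: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_seed_units <= 0 or self.n_outside_vertices <= 0:
            raise ValueError("unit counts must be positive")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        props = tuple(float(p) for p in self.band_proportions)
        if len(props) != 3 or any(p < 0 for p in props):
            raise ValueError("band_proportions must be 3 non-negative fractions")
        if abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("band_proportions must sum to 1")
        if any(p == 0 for p in props):
            raise ValueError("zero band proportion gives a degenerate phantom")
        if len(self.target_names) != 42:
            raise ValueError("exactly 42 target names required")
        if self.n_timepoints <= 0 or self.n_streamlines_per_unit <= 0:
            raise ValueError("n_timepoints and n_streamlines_per_unit must be positive")
        object.__setattr__(self, "band_proportions", props)
        object.__setattr__(self, "target_names", tuple(self.target_names))

    def noise_free(self) -> "PhantomConfig":
        """Copy with every stochastic perturbation switched off."""
        return replace(
            self,
            fingerprint_concentration=np.inf,
            sample_streamlines=False,
            timeseries_noise_sd=0.0,
            outside_noise_sd=0.0,
            myelin_sd=0.0,
            thickness_sd=0.0,
            boundary_jitter_sd=0.0,
        )


@dataclass
class Phantom:
    """Seed-region geometry with planted subregion labels and neighbors."""

    coordinates: np.ndarray  # (n, 3) mm, integer lattice positions
    true_labels: np.ndarray  # (n,) in BAND_NAMES
    axis_coordinate: np.ndarray  # (n,) in [0, 1]
    neighbor_coordinates: np.ndarray  # (m, 3) mm, off-seed lattice positions
    neighbor_labels: np.ndarray  # (m,) region names (STG, IN, SPG, ...)
    hemisphere: str = "left"

    def __post_init__(self):
        axis = np.asarray(self.axis_coordinate, dtype=float)
        if np.any(axis < 0) or np.any(axis > 1):
            raise ValueError("axis_coordinate must lie in [0, 1]")
        self.axis_coordinate = axis
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.true_labels = np.asarray(self.true_labels)
        self.neighbor_coordinates = np.asarray(self.neighbor_coordinates, dtype=float)
        self.neighbor_labels = np.asarray(self.neighbor_labels)

    @property
    def n_units(self) -> int:
        return self.coordinates.shape[0]

    def seed_region(self) -> SeedRegion:
        ids = np.arange(self.n_units)
        return SeedRegion(self.coordinates, ids, self.hemisphere)


@dataclass
class SubjectBundle:
    subject_id: str
    phantom: Phantom
    fingerprint: Fingerprint
    timeseries: TimeSeriesBundle
    morphometry: MorphometryMaps
    rng_seed: int


@dataclass
class Cohort:
    subjects: list
    shared_mesh: bool
    rng_seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Integer band sizes from fractions, apportioned by largest remainder."""
    props = np.asarray(proportions, dtype=float)
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _lattice(n: int, width_y: int = 5, width_z: int = 4):
    """Integer mm lattice filling an elongated box, ordered along its long
    (x) axis. Returns coordinates and per-unit axis rank."""
    per_slice = width_y * width_z
    length = math.ceil(n / per_slice)
    xs, ys, zs = np.meshgrid(
        np.arange(length), np.arange(width_y), np.arange(width_z), indexing="ij"
    )
    coords = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]).astype(float)
    return coords[:n]


def _neighbor_shell(n: int, width_y: int = 5, width_z: int = 4):
    """Off-seed lattice layers: STG lateral to the box (y > max), insula
    medial (y < 0), SPG superior (z > max). Layer k sits k mm from the
    nearest seed face."""
    length = math.ceil(n / (width_y * width_z))
    coords, labels = [], []
    for layer in (1, 2, 3):
        for x in range(length):
            for z in range(width_z):
                coords.append([x, width_y - 1 + layer, z])
                labels.append("STG")
                coords.append([x, -layer, z])
                labels.append("IN")
    for layer in (1, 2):
        for x in range(length):
            for y in range(width_y):
                coords.append([x, y, width_z - 1 + layer])
                labels.append("SPG")
    return np.asarray(coords, dtype=float), np.asarray(labels, dtype=object)


def make_phantom(config: PhantomConfig, rng=None) -> Phantom:
    """Build the lattice phantom with axis-ordered planted bands.

    Band sizes follow largest-remainder rounding of ``band_proportions``;
    the two cut points are jittered per subject (Gaussian,
    ``boundary_jitter_sd`` in axis units, truncated so no band empties).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.n_seed_units
    coords = _lattice(n)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    axis = (rank + 0.5) / n

    sizes = dict(zip(BAND_NAMES, largest_remainder_counts(n, config.band_proportions)))
    cut1 = sizes["HG2"]
    cut2 = sizes["HG2"] + sizes["HG1"]
    if config.boundary_jitter_sd > 0:
        jitter = rng.normal(0.0, config.boundary_jitter_sd * n, size=2)
        cut1 = int(round(cut1 + jitter[0]))
        cut2 = int(round(cut2 + jitter[1]))
        cut1 = min(max(cut1, 1), n - 2)
        cut2 = min(max(cut2, cut1 + 1), n - 1)
    labels = np.where(rank < cut1, "HG2", np.where(rank < cut2, "HG1", "HG3"))

    neighbor_coords, neighbor_labels = _neighbor_shell(n)
    if config.hemisphere == "right":
        coords = coords.copy()
        neighbor_coords = neighbor_coords.copy()
        coords[:, 1] *= -1
        neighbor_coords[:, 1] *= -1
    return Phantom(coords, labels, axis, neighbor_coords, neighbor_labels,
                   config.hemisphere)


# Additive target weights on top of a uniform background of 1 per target.
# HG3 is biased toward STG, HG2 toward insula/SMG/SPG, HG1 intermediate.
_BAND_BOOSTS = {
    "HG1": {"STG": 6.0, "IN": 5.0, "SMG": 4.0, "SPG": 2.5},
    "HG2": {"STG": 2.0, "IN": 8.0, "SMG": 6.0, "SPG": 4.0},
    "HG3": {"STG": 10.0, "IN": 2.0, "SMG": 2.0, "SPG": 1.0},
}


def band_base_profiles(target_names=DEFAULT_TARGETS) -> dict:
    """Row-stochastic base connection profile per band."""
    profiles = {}
    for band in BAND_NAMES:
        w = np.ones(len(target_names))
        for t, boost in _BAND_BOOSTS[band].items():
            w[list(target_names).index(t)] += boost
        profiles[band] = w / w.sum()
    return profiles


def simulate_fingerprints(phantom: Phantom, config: PhantomConfig, rng=None) -> Fingerprint:
    """Multinomial streamline-count fingerprints from band base profiles.

    Per unit the band profile is perturbed by a Dirichlet draw with
    concentration ``fingerprint_concentration * profile`` and then
    ``n_streamlines_per_unit`` endpoints are drawn multinomially, so every
    row sums exactly to the streamline budget.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    base = band_base_profiles(config.target_names)
    for band, p in base.items():
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"base profile for {band} is not row-stochastic")
    n_stream = config.n_streamlines_per_unit
    rows = np.empty((phantom.n_units, len(config.target_names)))
    for i, band in enumerate(phantom.true_labels):
        p = base[band]
        if np.isfinite(config.fingerprint_concentration):
            p = rng.dirichlet(config.fingerprint_concentration * p)
        if config.sample_streamlines:
            rows[i] = rng.multinomial(n_stream, p)
        else:
            rows[i] = n_stream * p
    return Fingerprint(rows, config.target_names, "raw")


def simulate_timeseries(phantom: Phantom, config: PhantomConfig, rng=None) -> TimeSeriesBundle:
    """Two-latent mixing model planting an axis-graded connectivity pattern.

    Outside vertices belong to one of two latent networks via their target
    ROI (association targets follow latent B); each seed vertex mixes the
    latents as (1 - g) * A + g * B with g its axis coordinate, plus
    Gaussian noise.
    """
    if config.n_timepoints < 10:
        raise ValueError("need at least 10 timepoints for correlations")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    T = config.n_timepoints
    latent_a = rng.standard_normal(T)
    latent_b = rng.standard_normal(T)

    targets = config.target_names
    membership = np.array(
        [targets[v % len(targets)] for v in range(config.n_outside_vertices)],
        dtype=object,
    )
    is_assoc = np.array([t in ASSOCIATION_TARGETS for t in membership])
    outside = np.where(is_assoc[:, None], latent_b, latent_a) + (
        config.outside_noise_sd
        * rng.standard_normal((config.n_outside_vertices, T))
    )

    g = phantom.axis_coordinate[:, None]
    seed = (1.0 - g) * latent_a + g * latent_b + (
        config.timeseries_noise_sd * rng.standard_normal((phantom.n_units, T))
    )
    assoc = tuple(t for t in targets if t in ASSOCIATION_TARGETS)
    return TimeSeriesBundle(seed, outside, membership, targets,
                            association_targets=assoc)


# Population means for the morphometry maps; thickness order of HG2/HG3
# flips between hemispheres while HG1 stays largest in both measures.
MYELIN_MEANS = {"HG1": 1.80, "HG2": 1.55, "HG3": 1.48}
THICKNESS_MEANS = {
    "left": {"HG1": 2.95, "HG2": 2.70, "HG3": 2.50},
    "right": {"HG1": 2.95, "HG2": 2.50, "HG3": 2.70},
}


def simulate_morphometry(phantom: Phantom, config: PhantomConfig, rng=None) -> MorphometryMaps:
    """Gaussian per-unit myelin/thickness around band- and hemisphere-
    specific means."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    th_means = THICKNESS_MEANS[config.hemisphere]
    myelin = np.array([MYELIN_MEANS[b] for b in phantom.true_labels])
    thickness = np.array([th_means[b] for b in phantom.true_labels])
    myelin = myelin + config.myelin_sd * rng.standard_normal(phantom.n_units)
    thickness = thickness + config.thickness_sd * rng.standard_normal(phantom.n_units)
    return MorphometryMaps(myelin, np.clip(thickness, 0.1, None))


def make_cohort(n_subjects: int, config: PhantomConfig) -> Cohort:
    """Generate a cohort on a shared seed mesh.

    Per-subject generators are spawned deterministically from the master
    seed, so a fixed master seed reproduces the cohort bit for bit.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for paired contrasts")
    master = np.random.SeedSequence(config.rng_seed)
    subjects = []
    for i, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        phantom = make_phantom(config, rng)
        fp = simulate_fingerprints(phantom, config, rng)
        ts = simulate_timeseries(phantom, config, rng)
        morph = simulate_morphometry(phantom, config, rng)
        subjects.append(
            SubjectBundle(f"sub-{i:03d}", phantom, fp, ts, morph, rng_seed=i)
        )
    return Cohort(subjects, shared_mesh=True, rng_seed=config.rng_seed)
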