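"""Synthetic cohorts with exact ground truth.

Emulates the study design at desk scale: a labelled parcellation with
resting-state-network assignments, a healthy reference connectome of integer
streamline counts (minimum non-zero value 1), piecewise-linear streamlines
terminating in parcel pairs, and a lesion that evolves over three sessions
(shrinkage, optional boundary shift and transient regrowth).

Design:

* parcels are Voronoi cells of seed voxels, so every parcel is non-empty;
* streamlines are quadratic Bezier curves between random points in two
  different parcels, stored pre-densified at <= 0.9-voxel spacing so no
  voxel can be skipped by any later intersection test;
* lesions are spheres (voxel-center within radius of a possibly jittered
  center), which gives analytic control of nesting and volume;
* one master seed; each stage draws from an independently spawned child
  stream, so adding a stage never perturbs earlier ones.

Ground-truth disconnection fractions are computed by an exhaustive
per-streamline, per-point voxel-membership walk, written independently of
:mod:`disconnectome.engine` so it can serve as that module's oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .core import LesionMask, ParcellationAtlas, StreamlineSet
from .errors import ConfigurationError, GenerationError

__all__ = [
    "LesionSpec",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_atlas",
    "generate_streamlines",
    "generate_lesions",
    "generate_cohort",
    "true_disconnection_fractions",
    "transition_pairs",
]

_STREAMLINE_SPACING = 0.9  # voxels; strictly below the engine's 1.0 densification


@dataclass(frozen=True)
class LesionSpec:
    """One timepoint of lesion evolution: a sphere in voxel coordinates."""

    center: tuple[float, float, float]
    radius: float
    jitter: float = 0.0  # uniform center displacement bound (voxels)


def _default_lesion_specs() -> tuple[LesionSpec, ...]:
    # three sessions, strictly shrinking around a fixed center: the nested
    # no-jitter reference condition (cf. Table-2-style volume reduction)
    c = (16.0, 16.0, 16.0)
    return (LesionSpec(c, 8.0), LesionSpec(c, 5.5), LesionSpec(c, 3.0))


@dataclass(frozen=True)
class CohortConfig:
    """Reproducible synthetic-cohort recipe.

    Defaults describe the standard desk-scale cohort: a 32 mm-cube grid at
    1 mm isotropic, 60 parcels in 10 networks, 600 reference streamlines and
    a nested shrinking lesion observed at three sessions S1..S3.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 1.0
    n_parcels: int = 60
    n_networks: int = 10
    n_streamlines: int = 600
    lesion_specs: tuple[LesionSpec, ...] = field(default_factory=_default_lesion_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be three positive integers")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")
        if self.n_parcels < 1 or self.n_streamlines < 1:
            raise ConfigurationError("n_parcels and n_streamlines must be positive")
        if not 1 <= self.n_networks <= self.n_parcels:
            raise ConfigurationError("need 1 <= n_networks <= n_parcels")
        if len(self.lesion_specs) < 2:
            raise ConfigurationError("need >= 2 lesion timepoints to form a transition")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "lesion_specs", tuple(self.lesion_specs))

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(f"S{k + 1}" for k in range(len(self.lesion_specs)))

    def child_rngs(self) -> dict[str, np.random.Generator]:
        """Independent per-stage generators derived from the master seed."""
        atlas_ss, stream_ss, lesion_ss = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "atlas": np.random.default_rng(atlas_ss),
            "streamlines": np.random.default_rng(stream_ss),
            "lesions": np.random.default_rng(lesion_ss),
        }


@dataclass
class GroundTruth:
    """Exact per-timepoint truth for a synthetic cohort.

    ``disconnection_fraction_true[t]`` is a symmetric P x P matrix in [0, 1];
    ``edge_category_true[(a, b)]`` maps each unordered parcel pair with a
    healthy connection to its longitudinal category for timepoint transition
    a -> b (0-based indices), under the primary 10% over-connection threshold.
    """

    disconnection_fraction_true: list[np.ndarray]
    lesion_volume_true: list[float]
    edge_category_true: dict[tuple[int, int], dict[tuple[int, int], str]]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    atlas: ParcellationAtlas
    streamlines: StreamlineSet
    healthy: np.ndarray
    masks: list[LesionMask]
    truth: GroundTruth


def transition_pairs(n_timepoints: int) -> list[tuple[int, int]]:
    """Analysis transitions: consecutive sessions plus first-to-last.

    Three sessions yield (0,1), (1,2), (0,2) - early stage, late stage, and
    overall recovery.
    """
    pairs = [(k, k + 1) for k in range(n_timepoints - 1)]
    if n_timepoints > 2:
        pairs.append((0, n_timepoints - 1))
    return pairs


def generate_atlas(config: CohortConfig, rng: np.random.Generator | None = None) -> ParcellationAtlas:
    """Voronoi parcellation: every voxel joins its nearest seed voxel's parcel.

    Parcels are guaranteed non-empty (each seed voxel is its own nearest
    seed); networks are assigned round-robin, so all ``n_networks`` names are
    used whenever ``n_parcels >= n_networks``.
    """
    if rng is None:
        rng = config.child_rngs()["atlas"]
    shape = config.grid_shape
    n_vox = int(np.prod(shape))
    if config.n_parcels > n_vox:
        raise ConfigurationError(
            f"cannot host {config.n_parcels} parcels on a {n_vox}-voxel grid"
        )
    seed_flat = rng.choice(n_vox, size=config.n_parcels, replace=False)
    seeds = np.column_stack(np.unravel_index(seed_flat, shape)).astype(float)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    _, nearest = cKDTree(seeds).query(grid, k=1)
    labels = (nearest + 1).astype(np.int32).reshape(shape)
    networks = {
        p: f"RSN{(p - 1) % config.n_networks + 1:02d}"
        for p in range(1, config.n_parcels + 1)
    }
    return ParcellationAtlas(labels=labels, voxel_size=config.voxel_size, networks=networks)


def _bezier(a: np.ndarray, c: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * a + 2 * t * (1 - t) * c + t**2 * b


def generate_streamlines(
    atlas: ParcellationAtlas, config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[StreamlineSet, np.ndarray]:
    """Curved polylines between random parcel pairs plus the healthy connectome.

    Returns the streamline set and the symmetric P x P integer count matrix
    ``healthy`` with ``healthy[i-1, j-1]`` = number of streamlines whose
    endpoints fall in parcels i and j. Endpoint pairs with a single
    streamline give the matrix its minimum non-zero value of 1.
    """
    if rng is None:
        rng = config.child_rngs()["streamlines"]
    shape = np.asarray(config.grid_shape)
    labels = atlas.labels
    p = atlas.n_parcels
    polylines: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    budget = 50 * config.n_streamlines
    while len(polylines) < config.n_streamlines:
        if budget <= 0:
            raise GenerationError("retry budget exhausted while placing streamlines")
        budget -= 1
        a_vox = rng.integers(0, shape)
        b_vox = rng.integers(0, shape)
        la = int(labels[tuple(a_vox)])
        lb = int(labels[tuple(b_vox)])
        if la == 0 or lb == 0 or la == lb:
            continue
        a = a_vox + rng.uniform(0.0, 1.0, size=3)
        b = b_vox + rng.uniform(0.0, 1.0, size=3)
        chord = float(np.linalg.norm(b - a))
        ctrl = (a + b) / 2 + rng.normal(0.0, chord / 6 + 1e-9, size=3)
        n_samples = max(3, int(math.ceil(chord * 2)) + 1)
        pts = _bezier(a, ctrl, b, n_samples)
        np.clip(pts, 0.0, shape - 1e-6, out=pts)
        pts = _densify(pts, _STREAMLINE_SPACING)
        first = tuple(np.floor(pts[0]).astype(int))
        last = tuple(np.floor(pts[-1]).astype(int))
        if int(labels[first]) != la or int(labels[last]) != lb:
            continue
        polylines.append(pts)
        pairs.append((min(la, lb), max(la, lb)))
    healthy = np.zeros((p, p), dtype=np.int64)
    for i, j in pairs:
        healthy[i - 1, j - 1] += 1
        healthy[j - 1, i - 1] += 1
    return StreamlineSet(streamlines=polylines, endpoints=np.array(pairs)), healthy


def _densify(pts: np.ndarray, max_spacing: float) -> np.ndarray:
    # local copy of the piecewise-linear refinement (keeps the generator
    # independent of the engine it is used to test)
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        d = float(np.linalg.norm(b - a))
        n = max(1, int(math.ceil(d / max_spacing)))
        frac = np.arange(1, n + 1)[:, None] / n
        out.append(a + (b - a) * frac)
    return np.concatenate(out, axis=0)


def _sphere_mask(shape: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(shape, dtype=bool)
    if not _sphere_touches_box(center, radius, shape):
        raise ConfigurationError("lesion sphere lies entirely outside the grid")
    centers = np.indices(shape).reshape(3, -1).T + 0.5
    inside = np.linalg.norm(centers - center, axis=1) <= radius
    return inside.reshape(shape)


def _sphere_touches_box(center: np.ndarray, radius: float, shape: tuple[int, int, int]) -> bool:
    nearest = np.clip(center, 0.0, np.asarray(shape, float))
    return float(np.linalg.norm(nearest - center)) <= radius


def generate_lesions(
    config: CohortConfig,
    streamlines: StreamlineSet | None = None,
    healthy: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> tuple[list[LesionMask], GroundTruth]:
    """Spherical lesion masks per timepoint plus exact ground truth.

    With ``jitter > 0`` the sphere center is displaced uniformly in
    ``[-jitter, jitter]`` per axis, emulating boundary shift (DSC < 1);
    a radius sequence that dips and rises (e.g. 3, 2, 3) emulates transient
    regrowth. Ground-truth disconnection fractions and edge categories are
    filled in only when ``streamlines`` and ``healthy`` are supplied;
    volumes are always exact: voxel count x voxel_size^3.
    """
    if rng is None:
        rng = config.child_rngs()["lesions"]
    shape = config.grid_shape
    masks: list[LesionMask] = []
    for label, spec in zip(config.timepoints, config.lesion_specs):
        center = np.asarray(spec.center, dtype=float)
        if spec.jitter > 0:
            center = center + rng.uniform(-spec.jitter, spec.jitter, size=3)
        data = _sphere_mask(shape, center, spec.radius)
        masks.append(
            LesionMask(data=data, voxel_size=config.voxel_size,
                       timepoint=label, subject_id=subject_id)
        )
    volumes = [m.n_voxels * config.voxel_size**3 for m in masks]
    fractions: list[np.ndarray] = []
    categories: dict[tuple[int, int], dict[tuple[int, int], str]] = {}
    if streamlines is not None and healthy is not None:
        for m in masks:
            fractions.append(true_disconnection_fractions(streamlines, healthy, m.data))
        for a, b in transition_pairs(len(masks)):
            categories[(a, b)] = _true_categories(healthy, fractions[a], fractions[b])
    return masks, GroundTruth(
        disconnection_fraction_true=fractions,
        lesion_volume_true=volumes,
        edge_category_true=categories,
    )


def true_disconnection_fractions(
    streams: StreamlineSet, healthy: np.ndarray, mask_data: np.ndarray
) -> np.ndarray:
    """Exhaustive oracle: per-pair intercepted proportion by plain point walk.

    Visits every stored polyline point, floors it to a voxel and checks
    lesion membership - no densification, no vectorisation, no shared code
    with the engine.
    """
    mask_data = np.asarray(mask_data).astype(bool)
    shape = mask_data.shape
    p = np.asarray(healthy).shape[0]
    hit_count: dict[tuple[int, int], int] = {}
    for pts, (i, j) in zip(streams.streamlines, streams.endpoints):
        hit = False
        for point in pts:
            vx = (min(int(math.floor(point[0])), shape[0] - 1),
                  min(int(math.floor(point[1])), shape[1] - 1),
                  min(int(math.floor(point[2])), shape[2] - 1))
            if mask_data[vx]:
                hit = True
                break
        if hit:
            key = (min(int(i), int(j)), max(int(i), int(j)))
            hit_count[key] = hit_count.get(key, 0) + 1
    frac = np.zeros((p, p), dtype=float)
    for (i, j), n_hit in hit_count.items():
        f = n_hit / healthy[i - 1, j - 1]
        frac[i - 1, j - 1] = f
        frac[j - 1, i - 1] = f
    return frac


def _true_categories(
    healthy: np.ndarray, frac_a: np.ndarray, frac_b: np.ndarray,
    over_threshold_pct: float = 10.0,
) -> dict[tuple[int, int], str]:
    """Longitudinal edge categories from ground-truth fractions (plain loops)."""
    p = healthy.shape[0]
    out: dict[tuple[int, int], str] = {}
    for i in range(1, p + 1):
        for j in range(i + 1, p + 1):
            h = healthy[i - 1, j - 1]
            if h <= 0:
                continue
            wa = h * (1.0 - frac_a[i - 1, j - 1])
            wb = h * (1.0 - frac_b[i - 1, j - 1])
            if wa > 0 and wb == 0:
                cat = "disconnection"
            elif wa == 0 and wb > 0:
                cat = "re-emerging"
            elif wa == 0 and wb == 0:
                cat = "absent-both"
            elif (wb - wa) / wa * 100.0 > over_threshold_pct:
                cat = "over-connection"
            else:
                cat = "persistent-other"
            out[(i, j)] = cat
    return out


def generate_cohort(config: CohortConfig, subject_id: str = "sim") -> SyntheticCohort:
    """End-to-end synthesis: atlas, streamlines, healthy connectome, lesions, truth."""
    rngs = config.child_rngs()
    atlas = generate_atlas(config, rng=rngs["atlas"])
    streams, healthy = generate_streamlines(atlas, config, rng=rngs["streamlines"])
    masks, truth = generate_lesions(
        config, streamlines=streams, healthy=healthy, rng=rngs["lesions"],
        subject_id=subject_id,
    )
    return SyntheticCohort(
        config=config, atlas=atlas, streamlines=streams,
        healthy=healthy, masks=masks, truth=truth,
    )
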