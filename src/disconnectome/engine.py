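"""Streamline-lesion interception and patient-weighted connectivity.

For every parcel pair the engine counts how many reference streamlines are
intercepted by a lesion mask. The intercepted proportion is the
*disconnection fraction*; its complement is the *spared fraction*, and the
patient-specific weighted connectome is the healthy streamline count scaled
by the spared fraction at each timepoint:

    weighted(i, j, t) = healthy(i, j) * spared(i, j, t)

A streamline is intercepted if ANY of its points, after densification to at
most one-voxel spacing, falls in a lesion voxel - the most sensitive reading
of "intercepted"; no minimum overlap length is required. Point-to-voxel
membership is ``floor`` of the voxel-frame coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LesionMask, StreamlineSet
from .errors import ValidationError

__all__ = [
    "densify_polyline",
    "streamline_voxels",
    "streamline_intercepted",
    "intercepted_streamlines",
    "SparedFractionMatrix",
    "disconnection_fractions",
    "weight_patient",
    "binarize",
]


def densify_polyline(points: np.ndarray, max_spacing: float = 1.0) -> np.ndarray:
    """Insert points along each segment so consecutive spacing <= max_spacing.

    Segments already shorter than ``max_spacing`` are kept untouched, so a
    polyline that is dense enough passes through unchanged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValidationError("empty polyline")
    pts = pts.reshape(-1, 3)
    if len(pts) == 1:
        return pts
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        d = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(d / max_spacing)))
        frac = np.arange(1, n + 1)[:, None] / n
        out.append(a + (b - a) * frac)
    return np.concatenate(out, axis=0)


def streamline_voxels(points: np.ndarray, grid_shape: tuple[int, int, int],
                      max_spacing: float = 1.0) -> np.ndarray:
    """0-based voxel indices visited by the densified polyline, (n, 3) int."""
    dense = densify_polyline(points, max_spacing=max_spacing)
    idx = np.floor(dense).astype(np.int64)
    # points exactly on the far grid face belong to the last voxel
    return np.clip(idx, 0, np.asarray(grid_shape) - 1)


def streamline_intercepted(points: np.ndarray, mask: LesionMask | np.ndarray,
                           max_spacing: float = 1.0) -> bool:
    """True iff any densified point of the polyline lies in a lesion voxel."""
    data = mask.data if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    idx = streamline_voxels(points, data.shape, max_spacing=max_spacing)
    return bool(data[idx[:, 0], idx[:, 1], idx[:, 2]].any())


def intercepted_streamlines(streams: StreamlineSet, mask: LesionMask | np.ndarray,
                            max_spacing: float = 1.0) -> np.ndarray:
    """Boolean vector: which streamlines the lesion intercepts."""
    data = mask.data if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    if not data.any():  # empty lesion intercepts nothing
        return np.zeros(len(streams), dtype=bool)
    return np.fromiter(
        (streamline_intercepted(pts, data, max_spacing) for pts in streams.streamlines),
        dtype=bool, count=len(streams),
    )


@dataclass(frozen=True)
class SparedFractionMatrix:
    """Per-pair spared/disconnection fractions for one timepoint.

    ``spared + disconnection == 1`` elementwise; pairs with no healthy
    streamlines carry spared 1 (nothing to intercept). Both are symmetric.
    """

    spared: np.ndarray
    disconnection: np.ndarray


def disconnection_fractions(streams: StreamlineSet, healthy: np.ndarray,
                            mask: LesionMask | np.ndarray) -> SparedFractionMatrix:
    """Fraction of each parcel pair's reference streamlines hit by the lesion.

    Parameters
    ----------
    streams
        Reference streamlines with declared endpoint parcel pairs.
    healthy
        P x P healthy streamline-count matrix; ``healthy[i-1, j-1]`` must equal
        the number of streamlines with endpoint pair ``{i, j}``.
    mask
        Binary lesion mask on the same grid.

    Raises
    ------
    ValidationError
        If a streamline's endpoint pair is absent from the healthy matrix.
    """
    healthy = np.asarray(healthy)
    p = healthy.shape[0]
    hits = intercepted_streamlines(streams, mask)
    intercepted = np.zeros((p, p), dtype=np.int64)
    for hit, (i, j) in zip(hits, streams.endpoints):
        if healthy[i - 1, j - 1] <= 0:
            raise ValidationError(
                f"streamline endpoint pair ({i}, {j}) absent from healthy connectome"
            )
        if hit:
            intercepted[i - 1, j - 1] += 1
            intercepted[j - 1, i - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.where(healthy > 0, intercepted / np.maximum(healthy, 1), 0.0)
    spared = 1.0 - disc
    return SparedFractionMatrix(spared=spared, disconnection=disc)


def weight_patient(healthy: np.ndarray, spared: SparedFractionMatrix | np.ndarray) -> np.ndarray:
    """Patient-weighted connectome: healthy counts scaled by spared fractions."""
    sp = spared.spared if isinstance(spared, SparedFractionMatrix) else np.asarray(spared, float)
    healthy = np.asarray(healthy)
    if sp.shape != healthy.shape:
        raise ValidationError("spared matrix shape does not match healthy connectome")
    if np.any(sp < 0) or np.any(sp > 1):
        raise ValidationError("spared fractions must lie in [0, 1]")
    return healthy * sp


def binarize(weighted: np.ndarray) -> np.ndarray:
    """Binary connectome: 1 exactly where the weight is strictly positive."""
    w = np.asarray(weighted)
    if np.any(w < 0):
        raise ValidationError("weighted connectome must be non-negative")
    return (w > 0).astype(np.int8)
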