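"""Shared spatial containers: parcellation atlas, streamline set, lesion mask.

Conventions used throughout the package:

* All spatial data live on one voxel grid in "voxel frame" coordinates:
  a continuous point ``p`` belongs to voxel ``floor(p)`` (0-based indices).
  Affines exist only at NIfTI I/O.
* Parcels are labelled 1..P; label 0 is background.
* Connectivity matrices are dense ``P x P`` numpy arrays indexed by
  ``parcel_id - 1``, symmetric with zero diagonal; all edge statistics are
  computed on the strict upper triangle (undirected edges, no self-connections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ParcellationAtlas", "StreamlineSet", "LesionMask", "triu_values"]


@dataclass(frozen=True)
class ParcellationAtlas:
    """Integer-labelled voxel grid plus a parcel -> network assignment.

    Parameters
    ----------
    labels
        3D integer array; 0 is background, parcels are 1..P with no gaps.
    voxel_size
        Isotropic voxel edge length in mm.
    networks
        Mapping from parcel id to resting-state-network name. Every parcel
        in ``labels`` must be mapped to exactly one network.
    """

    labels: np.ndarray
    voxel_size: float
    networks: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError("atlas label grid must be 3D")
        if self.voxel_size <= 0:
            raise ValidationError("voxel size must be positive")
        object.__setattr__(self, "labels", labels.astype(np.int32, copy=False))
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size == 0:
            raise ValidationError("atlas contains no parcels")
        p = int(present.max())
        if not np.array_equal(present, np.arange(1, p + 1)):
            raise ValidationError("parcel labels must be contiguous 1..P")
        missing = [int(i) for i in present if int(i) not in self.networks]
        if missing:
            raise ValidationError(f"parcels missing from network table: {missing}")

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max())

    @property
    def network_names(self) -> list[str]:
        return sorted(set(self.networks.values()))

    def network_vector(self) -> np.ndarray:
        """Network name per parcel, index k holds the network of parcel k+1."""
        return np.array([self.networks[p] for p in range(1, self.n_parcels + 1)])

    def parcel_volumes(self) -> np.ndarray:
        """Volume (mm^3) per parcel, index k -> parcel k+1."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_parcels + 1)
        return counts[1:] * self.voxel_size**3


@dataclass
class StreamlineSet:
    """Polyline streamlines with declared endpoint parcel pairs.

    ``streamlines[k]`` is an ``(n_k, 3)`` float array of ordered points in the
    atlas voxel frame; ``endpoints[k]`` is the unordered parcel pair
    ``(i, j)`` with ``i < j`` that the first and last points fall in.
    """

    streamlines: list[np.ndarray]
    endpoints: np.ndarray  # (n, 2) int

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=np.int64).reshape(-1, 2)
        if len(self.streamlines) != len(self.endpoints):
            raise ValidationError("one endpoint pair required per streamline")
        if np.any(self.endpoints[:, 0] == self.endpoints[:, 1]):
            raise ValidationError("self-pair streamlines are excluded")

    def __len__(self) -> int:
        return len(self.streamlines)

    def validate_against(self, atlas: ParcellationAtlas) -> None:
        """Check that declared endpoints match the parcels under the points."""
        lab = atlas.labels
        for pts, (i, j) in zip(self.streamlines, self.endpoints):
            a = tuple(np.floor(pts[0]).astype(int))
            b = tuple(np.floor(pts[-1]).astype(int))
            found = tuple(sorted((int(lab[a]), int(lab[b]))))
            if found != (int(i), int(j)):
                raise ValidationError(
                    f"streamline endpoints lie in parcels {found}, declared ({i}, {j})"
                )


@dataclass
class LesionMask:
    """Binary lesion mask on the atlas grid."""

    data: np.ndarray
    voxel_size: float
    timepoint: str = "S1"
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValidationError("lesion mask must be 3D")
        if not np.isin(np.unique(data), (0, 1)).all():
            raise ValidationError("lesion mask values must be 0/1")
        if self.voxel_size <= 0:
            raise ValidationError("voxel size must be positive")
        self.data = data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def triu_values(matrix: np.ndarray) -> np.ndarray:
    """Strict upper-triangle values of a square matrix (the edge vector)."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("expected a square matrix")
    return m[np.triu_indices(m.shape[0], k=1)]
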