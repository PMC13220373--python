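"""File formats: NIfTI volumes, polyline streamline text, connectome CSV.

The streamline text format is whitespace-delimited:

.. code-block:: text

    # disconnectome streamlines v1
    > 3 7
    1.25 2.50 0.75
    2.10 3.40 1.20
    <blank line>
    > 2 9
    ...

One ``> i j`` header per streamline giving its endpoint parcel ids, one
point per line in voxel-frame coordinates, streamlines separated by blank
lines. Connectivity matrices are CSV with parcel ids as both header row and
index column.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LesionMask, ParcellationAtlas, StreamlineSet
from .errors import ValidationError

__all__ = [
    "write_atlas_nifti", "read_atlas_nifti",
    "write_mask_nifti", "read_mask_nifti",
    "write_network_table", "read_network_table",
    "write_streamlines_text", "read_streamlines_text",
    "write_matrix_csv", "read_matrix_csv",
]


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def write_atlas_nifti(atlas: ParcellationAtlas, path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size))
    nib.save(img, str(path))


def read_atlas_nifti(path: str | Path, networks: dict[int, str]) -> ParcellationAtlas:
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return ParcellationAtlas(
        labels=np.asarray(img.dataobj).astype(np.int32),
        voxel_size=voxel_size,
        networks=networks,
    )


def write_mask_nifti(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size))
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path, timepoint: str = "S1",
                    subject_id: str = "") -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LesionMask(
        data=data,
        voxel_size=float(img.header.get_zooms()[0]),
        timepoint=timepoint,
        subject_id=subject_id,
    )


def write_network_table(networks: dict[int, str], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"parcel": sorted(networks), "network": [networks[k] for k in sorted(networks)]}
    )
    frame.to_csv(path, index=False)


def read_network_table(path: str | Path) -> dict[int, str]:
    frame = pd.read_csv(path)
    return dict(zip(frame["parcel"].astype(int), frame["network"].astype(str)))


def write_streamlines_text(streams: StreamlineSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# disconnectome streamlines v1\n")
        for pts, (i, j) in zip(streams.streamlines, streams.endpoints):
            fh.write(f"> {int(i)} {int(j)}\n")
            for x, y, z in pts:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            fh.write("\n")


def read_streamlines_text(path: str | Path) -> StreamlineSet:
    polylines: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    current: list[list[float]] = []
    pair: tuple[int, int] | None = None

    def _flush() -> None:
        nonlocal current, pair
        if pair is not None:
            if not current:
                raise ValidationError("streamline with no points")
            polylines.append(np.asarray(current, dtype=float))
            pairs.append(pair)
        current, pair = [], None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush()
                fields = line[1:].split()
                if len(fields) != 2:
                    raise ValidationError(f"malformed streamline header: {line!r}")
                pair = (int(fields[0]), int(fields[1]))
            else:
                current.append([float(v) for v in line.split()])
    _flush()
    if not polylines:
        raise ValidationError("no streamlines in file")
    return StreamlineSet(streamlines=polylines, endpoints=np.asarray(pairs))


def write_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    m = np.asarray(matrix)
    ids = np.arange(1, m.shape[0] + 1)
    pd.DataFrame(m, index=ids, columns=ids).to_csv(path, index_label="parcel")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, index_col=0)
    return frame.to_numpy(dtype=float)
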