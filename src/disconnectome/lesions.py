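"""Lesion quantification: volume, percent change, Dice overlap, NMI, lesion load.

Percent change follows the reduction-positive convention used in clinical
lesion-evolution tables: a shrinking lesion has a positive percent change,
a growing lesion a negative one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LesionMask, ParcellationAtlas
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "lesion_volume",
    "percent_change",
    "format_percent",
    "dice_coefficient",
    "normalized_mutual_information",
    "lesion_load_by_parcel",
    "network_lesion_load",
]


def lesion_volume(mask: LesionMask) -> float:
    """Lesion volume in mm^3: voxel count times voxel_size^3."""
    return mask.n_voxels * mask.voxel_size**3


def percent_change(v_earlier: float, v_later: float) -> float:
    """Signed percent volume change, reduction-positive.

    ``(v_earlier - v_later) / v_earlier * 100``: positive for lesion
    shrinkage, negative for growth. Undefined for a zero baseline volume.
    """
    if v_earlier < 0 or v_later < 0:
        raise ValidationError("volumes must be non-negative")
    if v_earlier == 0:
        raise DegenerateInputError("percent change undefined for zero baseline volume")
    return (v_earlier - v_later) / v_earlier * 100.0


def format_percent(value: float) -> str:
    """Display form: one decimal place, trailing '.0' dropped (54.01 -> '54')."""
    rounded = round(value, 1)
    if rounded == int(rounded):
        return str(int(rounded))
    return f"{rounded:.1f}"


def dice_coefficient(mask_a: LesionMask, mask_b: LesionMask) -> float:
    """Dice similarity coefficient 2|A&B| / (|A| + |B|).

    Two empty masks score 1 by convention (perfect agreement of nothing).
    """
    if mask_a.data.shape != mask_b.data.shape:
        raise ValidationError("masks must share a grid shape")
    size = mask_a.n_voxels + mask_b.n_voxels
    if size == 0:
        return 1.0
    inter = int(np.logical_and(mask_a.data, mask_b.data).sum())
    return 2.0 * inter / size


def normalized_mutual_information(
    image_a: np.ndarray, image_b: np.ndarray, n_bins: int = 64
) -> float:
    """Histogram NMI = (H(A) + H(B)) / H(A, B), used as registration QC.

    Equal-width bins over the pooled intensity range of both images. This
    normalisation is bounded in [1, 2]: independent images approach 1,
    identical (non-constant) images reach 2.
    """
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("images must share a shape")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant image has zero entropy; NMI undefined")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    joint, _, _ = np.histogram2d(a, b, bins=n_bins, range=[[lo, hi], [lo, hi]])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())
    return (_entropy(px) + _entropy(py)) / _entropy(pxy.ravel())


def lesion_load_by_parcel(mask: LesionMask, atlas: ParcellationAtlas) -> pd.DataFrame:
    """Damaged volume per parcel with a per-network rollup.

    Returns a long-format frame with columns ``parcel``, ``network`` and
    ``damaged_volume_mm3`` (parcel rows, zero-overlap parcels included)
    followed by per-network totals accessible via ``groupby``. Background
    overlap is not attributed to any parcel, so the parcel column sums to at
    most the lesion volume.
    """
    if mask.data.shape != atlas.labels.shape:
        raise ValidationError("mask and atlas must share a grid")
    p = atlas.n_parcels
    counts = np.bincount(atlas.labels[mask.data].ravel(), minlength=p + 1)
    vol = counts * mask.voxel_size**3
    frame = pd.DataFrame(
        {
            "parcel": np.arange(1, p + 1),
            "network": atlas.network_vector(),
            "damaged_volume_mm3": vol[1:],
        }
    )
    return frame


def network_lesion_load(load: pd.DataFrame) -> pd.DataFrame:
    """Per-network damaged volume summed over member parcels."""
    return (
        load.groupby("network", as_index=False)["damaged_volume_mm3"]
        .sum()
        .sort_values("network", ignore_index=True)
    )
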