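"""Longitudinal edge-change classification between two timepoints.

Every unordered parcel pair is assigned exactly one category from the
zero/non-zero status of its weights at the two sessions compared:

* ``disconnection``    - present earlier, absent later;
* ``re-emerging``      - absent earlier, present later;
* ``over-connection``  - positive at both, relative increase strictly above
  the threshold (primary 10%);
* ``persistent-other`` - positive at both, not an over-connection;
* ``absent-both``      - zero at both sessions.

The first three are the analysis categories and are mutually exclusive by
construction; relative change is ``(w_followup - w_baseline)/w_baseline x 100``
and is recorded only where both weights are positive. Normalised counts
divide each category's count by the number of existing connections at the
earlier timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LesionMask, triu_values
from .errors import DegenerateInputError, ValidationError
from .lesions import dice_coefficient, lesion_volume, percent_change

__all__ = [
    "CATEGORIES",
    "classify_edges",
    "ChangeCounts",
    "count_changes",
    "rsn_gain_loss",
    "lesion_covariate_table",
]

CATEGORIES = (
    "disconnection",
    "re-emerging",
    "over-connection",
    "persistent-other",
    "absent-both",
)


def classify_edges(
    w_a: np.ndarray,
    w_b: np.ndarray,
    over_threshold_pct: float = 10.0,
    network_of: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-edge transition table between weighted connectomes ``w_a -> w_b``.

    Returns one row per unordered parcel pair (strict upper triangle) with
    columns ``i``, ``j``, ``weight_baseline``, ``weight_followup``,
    ``category`` and ``relative_change_pct`` (NaN unless both weights are
    positive); ``network_i``/``network_j`` are added when a parcel-to-network
    mapping is supplied. The over-connection rule is a strict inequality:
    a relative increase of exactly the threshold is ``persistent-other``.
    """
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_a.shape != w_b.shape or w_a.ndim != 2 or w_a.shape[0] != w_a.shape[1]:
        raise ValidationError("weighted connectomes must be square and share a shape")
    if np.any(w_a < 0) or np.any(w_b < 0):
        raise ValidationError("weights must be non-negative")
    if over_threshold_pct <= 0:
        raise ValidationError("over-connection threshold must be positive")
    p = w_a.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    wa = w_a[iu, ju]
    wb = w_b[iu, ju]
    persistent = (wa > 0) & (wb > 0)
    rel = np.full(wa.shape, np.nan)
    rel[persistent] = (wb[persistent] - wa[persistent]) / wa[persistent] * 100.0
    category = np.where(
        (wa > 0) & (wb == 0), "disconnection",
        np.where(
            (wa == 0) & (wb > 0), "re-emerging",
            np.where(
                persistent & (rel > over_threshold_pct), "over-connection",
                np.where(persistent, "persistent-other", "absent-both"),
            ),
        ),
    )
    table = pd.DataFrame(
        {
            "i": iu + 1,
            "j": ju + 1,
            "weight_baseline": wa,
            "weight_followup": wb,
            "category": category,
            "relative_change_pct": rel,
        }
    )
    if network_of is not None:
        table["network_i"] = table["i"].map(network_of)
        table["network_j"] = table["j"].map(network_of)
    return table


@dataclass(frozen=True)
class ChangeCounts:
    """Absolute and normalised change counts for one transition."""

    n_disconnections: int
    n_reemerging: int
    n_overconnections: int
    n_existing_baseline: int
    pct_disconnections: float
    pct_reemerging: float
    pct_overconnections: float


def count_changes(table: pd.DataFrame, binary_a: np.ndarray) -> ChangeCounts:
    """Category counts, normalised by existing connections at baseline.

    ``binary_a`` is the baseline binary connectome; its strict-upper-triangle
    sum is the number of existing connections the normalised counts divide by.
    """
    n_existing = int(triu_values(np.asarray(binary_a)).sum())
    if n_existing == 0:
        raise DegenerateInputError(
            "no existing connections at baseline; normalised counts undefined"
        )
    counts = table["category"].value_counts()
    n_disc = int(counts.get("disconnection", 0))
    n_reem = int(counts.get("re-emerging", 0))
    n_over = int(counts.get("over-connection", 0))
    return ChangeCounts(
        n_disconnections=n_disc,
        n_reemerging=n_reem,
        n_overconnections=n_over,
        n_existing_baseline=n_existing,
        pct_disconnections=100.0 * n_disc / n_existing,
        pct_reemerging=100.0 * n_reem / n_existing,
        pct_overconnections=100.0 * n_over / n_existing,
    )


def rsn_gain_loss(table: pd.DataFrame, network_of: dict[int, str]) -> pd.DataFrame:
    """Connections gained/lost per RSN with dual attribution.

    Each re-emerging (gained) or disconnected (lost) edge is attributed to
    both endpoint networks; an intra-network edge counts once for its single
    network. Returns ``network``, ``gained``, ``lost``, ``difference``
    (gained - lost) for every network in the mapping.
    """
    networks = sorted(set(network_of.values()))
    gained = dict.fromkeys(networks, 0)
    lost = dict.fromkeys(networks, 0)
    for _, row in table[table["category"].isin(["re-emerging", "disconnection"])].iterrows():
        target = gained if row["category"] == "re-emerging" else lost
        nets = {network_of[int(row["i"])], network_of[int(row["j"])]}
        for net in nets:
            target[net] += 1
    return pd.DataFrame(
        {
            "network": networks,
            "gained": [gained[n] for n in networks],
            "lost": [lost[n] for n in networks],
            "difference": [gained[n] - lost[n] for n in networks],
        }
    )


def lesion_covariate_table(
    masks: list[LesionMask],
    counts: dict[tuple[int, int], ChangeCounts],
) -> pd.DataFrame:
    """Per-transition lesion-evolution covariates next to the change counts.

    For each transition ``(a, b)`` (0-based timepoint indices into ``masks``)
    the table reports the volume percent change (reduction-positive), the
    Dice coefficient between the two masks, the absolute and normalised
    category counts, and a re-emerging ratio defined as
    ``n_reemerging / (n_reemerging + n_disconnections)`` (NaN when there are
    no discrete changes).
    """
    if len(masks) < 2:
        raise ValidationError("need at least two timepoints")
    rows = []
    for (a, b), cc in counts.items():
        va = lesion_volume(masks[a])
        vb = lesion_volume(masks[b])
        discrete = cc.n_reemerging + cc.n_disconnections
        rows.append(
            {
                "transition": f"{masks[a].timepoint}-{masks[b].timepoint}",
                "volume_pct_change": percent_change(va, vb) if va > 0 else np.nan,
                "dsc": dice_coefficient(masks[a], masks[b]),
                "n_disconnections": cc.n_disconnections,
                "n_reemerging": cc.n_reemerging,
                "n_overconnections": cc.n_overconnections,
                "pct_disconnections": cc.pct_disconnections,
                "pct_reemerging": cc.pct_reemerging,
                "pct_overconnections": cc.pct_overconnections,
                "reemerging_ratio": cc.n_reemerging / discrete if discrete else np.nan,
            }
        )
    return pd.DataFrame(rows)
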