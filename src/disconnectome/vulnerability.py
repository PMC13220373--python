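"""Resting-state-network vulnerability: within/between connectivity loss.

Connectivity loss per parcel pair is the healthy streamline count minus the
patient-weighted count (equivalently healthy x disconnection fraction). Per
network, losses over intra-network pairs form the within-network sum and
losses over pairs with exactly one endpoint in the network form the
between-network sum; each is normalised by the network's own healthy total
and expressed as a percentage.

A cross-network pair contributes to BOTH endpoint networks' between sums,
so summing raw between losses over networks double-counts: the global
identity is

    sum_n within_raw(n) + 0.5 * sum_n between_raw(n) = total loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["connectivity_loss", "network_vulnerability"]

_ATOL = 1e-9


def connectivity_loss(healthy: np.ndarray, weighted: np.ndarray) -> np.ndarray:
    """Per-pair loss relative to the healthy connectome: healthy - weighted."""
    healthy = np.asarray(healthy, dtype=float)
    weighted = np.asarray(weighted, dtype=float)
    if healthy.shape != weighted.shape:
        raise ValidationError("healthy and weighted connectomes must share a shape")
    if np.any(weighted < -_ATOL):
        raise ValidationError("weighted connectome must be non-negative")
    if np.any(weighted > healthy + _ATOL):
        raise ValidationError("weighted connectome exceeds healthy counts")
    return np.clip(healthy - weighted, 0.0, None)


def network_vulnerability(
    loss: np.ndarray, healthy: np.ndarray, network_of: dict[int, str]
) -> pd.DataFrame:
    """Within- and between-network loss per RSN, raw and as percentages.

    Parameters
    ----------
    loss
        P x P symmetric loss matrix (from :func:`connectivity_loss`).
    healthy
        P x P healthy count matrix supplying the normalisation denominators.
    network_of
        Parcel id (1..P) -> network name; every parcel must be mapped.

    Returns
    -------
    DataFrame with one row per network: ``within_loss_raw``,
    ``between_loss_raw``, ``within_healthy``, ``between_healthy``,
    ``within_pct``, ``between_pct`` and a ``flags`` column marking zero
    denominators (those percentages are reported as 0).
    """
    loss = np.asarray(loss, dtype=float)
    healthy = np.asarray(healthy, dtype=float)
    p = loss.shape[0]
    missing = [k for k in range(1, p + 1) if k not in network_of]
    if missing:
        raise ValidationError(f"parcels missing a network assignment: {missing}")
    names = np.array([network_of[k] for k in range(1, p + 1)])
    rows = []
    for net in sorted(set(names)):
        member = names == net
        within_loss = float(loss[np.ix_(member, member)].sum() / 2.0)
        within_healthy = float(healthy[np.ix_(member, member)].sum() / 2.0)
        between_loss = float(loss[np.ix_(member, ~member)].sum())
        between_healthy = float(healthy[np.ix_(member, ~member)].sum())
        flags = []
        if within_healthy == 0:
            flags.append("zero_within_denominator")
        if between_healthy == 0:
            flags.append("zero_between_denominator")
        rows.append(
            {
                "network": net,
                "within_loss_raw": within_loss,
                "between_loss_raw": between_loss,
                "within_healthy": within_healthy,
                "between_healthy": between_healthy,
                "within_pct": 100.0 * within_loss / within_healthy if within_healthy else 0.0,
                "between_pct": 100.0 * between_loss / between_healthy if between_healthy else 0.0,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
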