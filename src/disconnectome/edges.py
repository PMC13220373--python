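"""Edge-level substantial-change analysis for persistent connections.

Persistent edges (weight > 0 at both sessions) are classed by their relative
change against a symmetric threshold (primary 10%): strictly above
+threshold is a substantial increase, strictly below -threshold a
substantial decrease, otherwise stable. To avoid inflated percentages from
near-zero baselines, edges whose baseline weight falls strictly below a
floor - the 5th percentile of all non-zero baseline edge weights of the
transition - are excluded from classification. Per network, the net change
is the number of increased minus decreased edges, with each inter-network
edge attributed to both endpoint networks (an intra-network edge counts once
for its network). A sensitivity sweep over thresholds (default 5/10/20%)
checks that each network's net-change sign is threshold independent; the
floor depends only on the baseline matrix and is identical across
thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import triu_values
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "baseline_floor",
    "classify_persistent",
    "net_change_by_network",
    "sensitivity_sweep",
]


def baseline_floor(w_baseline: np.ndarray, percentile: float = 5.0) -> float:
    """Minimum absolute baseline weight: percentile of non-zero edge weights.

    Uses linear interpolation between order statistics (numpy's default
    percentile definition); the variant is recorded in pipeline metadata.
    """
    vals = triu_values(np.asarray(w_baseline, dtype=float))
    vals = vals[vals > 0]
    if vals.size == 0:
        raise DegenerateInputError("all-zero baseline connectome; floor undefined")
    return float(np.percentile(vals, percentile, method="linear"))


def classify_persistent(
    w_a: np.ndarray,
    w_b: np.ndarray,
    threshold_pct: float = 10.0,
    floor: float | None = None,
    network_of: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Classify persistent edges by relative change against +/- threshold.

    Returns one row per persistent edge with ``i``, ``j``,
    ``weight_baseline``, ``weight_followup``, ``relative_change_pct``,
    ``floor``, ``floor_excluded`` and ``change_class`` in
    {substantial-increase, substantial-decrease, stable}; floor-excluded
    edges (baseline strictly below the floor) carry no class. A baseline
    exactly equal to the floor is retained.
    """
    if threshold_pct <= 0:
        raise ValidationError("threshold must be positive")
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_a.shape != w_b.shape:
        raise ValidationError("weighted connectomes must share a shape")
    if np.any(w_a < 0) or np.any(w_b < 0):
        raise ValidationError("weights must be non-negative")
    if floor is None:
        floor = baseline_floor(w_a)
    p = w_a.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    wa = w_a[iu, ju]
    wb = w_b[iu, ju]
    persistent = (wa > 0) & (wb > 0)
    wa = wa[persistent]
    wb = wb[persistent]
    rel = (wb - wa) / wa * 100.0
    excluded = wa < floor
    cls = np.where(
        rel > threshold_pct, "substantial-increase",
        np.where(rel < -threshold_pct, "substantial-decrease", "stable"),
    ).astype(object)
    cls[excluded] = None
    table = pd.DataFrame(
        {
            "i": iu[persistent] + 1,
            "j": ju[persistent] + 1,
            "weight_baseline": wa,
            "weight_followup": wb,
            "relative_change_pct": rel,
            "floor": floor,
            "floor_excluded": excluded,
            "change_class": cls,
        }
    )
    if network_of is not None:
        table["network_i"] = table["i"].map(network_of)
        table["network_j"] = table["j"].map(network_of)
    return table


def net_change_by_network(table: pd.DataFrame, network_of: dict[int, str]) -> pd.DataFrame:
    """Net substantial change per network with dual attribution.

    Each classed edge contributes to both endpoint networks (once only when
    both endpoints share a network). Returns ``network``, ``n_increase``,
    ``n_decrease``, ``net`` for every network in the mapping.
    """
    networks = sorted(set(network_of.values()))
    inc = dict.fromkeys(networks, 0)
    dec = dict.fromkeys(networks, 0)
    classed = table[~table["floor_excluded"] & table["change_class"].notna()]
    for _, row in classed.iterrows():
        if row["change_class"] == "substantial-increase":
            target = inc
        elif row["change_class"] == "substantial-decrease":
            target = dec
        else:
            continue
        for net in {network_of[int(row["i"])], network_of[int(row["j"])]}:
            target[net] += 1
    return pd.DataFrame(
        {
            "network": networks,
            "n_increase": [inc[n] for n in networks],
            "n_decrease": [dec[n] for n in networks],
            "net": [inc[n] - dec[n] for n in networks],
        }
    )


def sensitivity_sweep(
    w_a: np.ndarray,
    w_b: np.ndarray,
    thresholds: tuple[float, ...] = (5.0, 10.0, 20.0),
    network_of: dict[int, str] | None = None,
) -> tuple[dict[float, pd.DataFrame], pd.DataFrame]:
    """Net-change tables per threshold plus a sign-stability report.

    The baseline floor is recomputed at every threshold and - because it
    depends only on the baseline matrix - is identical across them. The
    stability report flags, per network, whether the sign of the net change
    is preserved across thresholds (zero nets are compatible with either
    sign).
    """
    if network_of is None:
        raise ValidationError("network mapping required for the sweep")
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValidationError("thresholds must be positive")
    per_threshold: dict[float, pd.DataFrame] = {}
    floors = []
    for thr in thresholds:
        floor = baseline_floor(w_a)  # recomputed per threshold, by construction equal
        floors.append(floor)
        classed = classify_persistent(w_a, w_b, threshold_pct=thr, floor=floor,
                                      network_of=network_of)
        per_threshold[float(thr)] = net_change_by_network(classed, network_of)
    assert len(set(floors)) == 1
    networks = per_threshold[float(thresholds[0])]["network"]
    signs = np.column_stack(
        [np.sign(per_threshold[float(t)]["net"].to_numpy()) for t in thresholds]
    )
    stable = [
        not (np.any(row > 0) and np.any(row < 0))
        for row in signs
    ]
    report = pd.DataFrame({"network": networks, "floor": floors[0]})
    for k, thr in enumerate(thresholds):
        report[f"net_at_{thr:g}pct"] = per_threshold[float(thr)]["net"].to_numpy()
        report[f"sign_at_{thr:g}pct"] = signs[:, k].astype(int)
    report["sign_stable"] = stable
    return per_threshold, report
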