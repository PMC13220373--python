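"""End-to-end pipeline: simulate or load inputs, run every analysis stage,
write the per-subject report bundle.

The bundle written to ``output_dir`` contains NIfTI inputs (uncompressed so
reruns are byte-identical), per-timepoint connectivity matrices, lesion
metrics, the RSN vulnerability table, per-transition edge tables and Fig-2
style summaries, per-threshold net-change tables, the sensitivity summary,
the lesion-evolution covariate table and a JSON manifest from which the
whole bundle can be regenerated (config + seed + package version).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, edges, io, lesions, transitions, vulnerability
from .core import LesionMask
from .engine import binarize, disconnection_fractions, weight_patient
from .errors import ConfigurationError, ValidationError
from .synthetic import CohortConfig, LesionSpec, generate_cohort, transition_pairs

__all__ = ["RunConfig", "SubjectRecord", "run_pipeline", "clinical_sidecar",
           "SCALE_RANGES"]

log = logging.getLogger("disconnectome")

SCALE_RANGES = {"mRS": (0, 5), "NIHSS": (0, 42), "BI": (0, 100), "FMA-UE": (0, 66)}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults reproduce the primary analysis
    (10% over-connection threshold, 5th-percentile floor, 5/10/20% sweep)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    subject_id: str = "sim-01"
    over_threshold_pct: float = 10.0
    sensitivity_thresholds: tuple[float, ...] = (5.0, 10.0, 20.0)
    floor_percentile: float = 5.0
    percentile_variant: str = "linear"
    output_dir: str | Path = "disconnectome_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cohort_raw = raw.pop("cohort", {})
            specs = cohort_raw.pop("lesion_specs", None)
            if specs is not None:
                cohort_raw["lesion_specs"] = tuple(
                    LesionSpec(tuple(s["center"]), float(s["radius"]),
                               float(s.get("jitter", 0.0)))
                    for s in specs
                )
            if "grid_shape" in cohort_raw:
                cohort_raw["grid_shape"] = tuple(cohort_raw["grid_shape"])
            thresholds = raw.pop("sensitivity_thresholds", None)
            cfg = cls(cohort=CohortConfig(**cohort_raw), **raw)
            if thresholds is not None:
                cfg = dataclasses.replace(
                    cfg, sensitivity_thresholds=tuple(float(t) for t in thresholds)
                )
        except (TypeError, KeyError) as exc:
            raise ConfigurationError(f"bad run configuration: {exc}") from exc
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


@dataclass
class SubjectRecord:
    """Timepoint labels, days post onset and optional clinical scores.

    ``scores`` maps scale name -> {timepoint -> value}; recognised scales and
    their valid ranges are in :data:`SCALE_RANGES` (mRS 0-5, NIHSS 0-42,
    BI 0-100, FMA-UE 0-66).
    """

    subject_id: str
    timepoints: list[str]
    days_post_onset: dict[str, int] | None = None
    scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for scale, per_tp in self.scores.items():
            if scale not in SCALE_RANGES:
                raise ValidationError(f"unknown clinical scale {scale!r}")
            lo, hi = SCALE_RANGES[scale]
            for tp, value in per_tp.items():
                if value is not None and not lo <= value <= hi:
                    raise ValidationError(
                        f"{scale} score {value} at {tp} outside [{lo}, {hi}]"
                    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle.

    Returns a dict with the in-memory results (cohort, matrices, tables) and
    the list of files written. Rerunning with the same config reproduces the
    bundle byte-identically.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run %s: generating cohort (seed %d)", config.subject_id, config.cohort.seed)

    cohort = generate_cohort(config.cohort, subject_id=config.subject_id)
    atlas, streams, healthy, masks = (
        cohort.atlas, cohort.streamlines, cohort.healthy, cohort.masks
    )
    tps = list(config.cohort.timepoints)
    files: list[str] = []

    def _write(name: str, writer) -> None:
        writer(out / name)
        files.append(name)

    _write("atlas.nii", lambda p: io.write_atlas_nifti(atlas, p))
    _write("networks.csv", lambda p: io.write_network_table(atlas.networks, p))
    _write("streamlines.txt", lambda p: io.write_streamlines_text(streams, p))
    _write("healthy_connectome.csv", lambda p: io.write_matrix_csv(healthy, p))
    for tp, mask in zip(tps, masks):
        _write(f"lesion_{tp}.nii", lambda p, m=mask: io.write_mask_nifti(m, p))

    # per-timepoint matrices
    weighted: dict[str, np.ndarray] = {}
    binary: dict[str, np.ndarray] = {}
    for tp, mask in zip(tps, masks):
        frac = disconnection_fractions(streams, healthy, mask)
        weighted[tp] = weight_patient(healthy, frac)
        binary[tp] = binarize(weighted[tp])
        _write(f"spared_{tp}.csv", lambda p, f=frac: io.write_matrix_csv(f.spared, p))
        _write(f"disconnection_{tp}.csv",
               lambda p, f=frac: io.write_matrix_csv(f.disconnection, p))
        _write(f"weighted_{tp}.csv", lambda p, w=weighted[tp]: io.write_matrix_csv(w, p))
        _write(f"binary_{tp}.csv", lambda p, b=binary[tp]: io.write_matrix_csv(b, p))

    # lesion metrics
    vols = [lesions.lesion_volume(m) for m in masks]
    metric_rows = []
    for k, tp in enumerate(tps):
        metric_rows.append(
            {
                "subject": config.subject_id,
                "timepoint": tp,
                "volume_mm3": vols[k],
                "pct_change_prev": lesions.percent_change(vols[k - 1], vols[k])
                if k > 0 and vols[k - 1] > 0 else np.nan,
                "pct_change_S1": lesions.percent_change(vols[0], vols[k])
                if k > 0 and vols[0] > 0 else np.nan,
                "dsc_prev": lesions.dice_coefficient(masks[k - 1], masks[k])
                if k > 0 else np.nan,
            }
        )
    metrics = pd.DataFrame(metric_rows)
    for col in ("pct_change_prev", "pct_change_S1"):
        metrics[col + "_display"] = [
            lesions.format_percent(v) if np.isfinite(v) else ""
            for v in metrics[col]
        ]
    _write("lesion_metrics.csv", lambda p: metrics.to_csv(p, index=False))

    load_frames = []
    for tp, mask in zip(tps, masks):
        load = lesions.lesion_load_by_parcel(mask, atlas)
        load.insert(0, "timepoint", tp)
        load_frames.append(load)
    _write("lesion_load.csv",
           lambda p: pd.concat(load_frames, ignore_index=True).to_csv(p, index=False))

    # vulnerability per timepoint
    vuln_frames = []
    for tp in tps:
        loss = vulnerability.connectivity_loss(healthy, weighted[tp])
        table = vulnerability.network_vulnerability(loss, healthy, atlas.networks)
        table.insert(0, "timepoint", tp)
        table.insert(0, "subject", config.subject_id)
        vuln_frames.append(table)
    vuln = pd.concat(vuln_frames, ignore_index=True)
    _write("vulnerability.csv", lambda p: vuln.to_csv(p, index=False))

    # transitions
    pairs = transition_pairs(len(tps))
    counts: dict[tuple[int, int], transitions.ChangeCounts] = {}
    edge_tables: dict[str, pd.DataFrame] = {}
    for a, b in pairs:
        label = f"{tps[a]}-{tps[b]}"
        table = transitions.classify_edges(
            weighted[tps[a]], weighted[tps[b]],
            over_threshold_pct=config.over_threshold_pct,
            network_of=atlas.networks,
        )
        edge_tables[label] = table
        counts[(a, b)] = transitions.count_changes(table, binary[tps[a]])
        _write(f"edges_{label}.csv", lambda p, t=table: t.to_csv(p, index=False))
        gl = transitions.rsn_gain_loss(table, atlas.networks)
        _write(f"rsn_gain_loss_{label}.csv", lambda p, t=gl: t.to_csv(p, index=False))

    summary_rows = []
    for (a, b), cc in counts.items():
        label = f"{tps[a]}-{tps[b]}"
        floor = edges.baseline_floor(weighted[tps[a]], config.floor_percentile)
        classed = edges.classify_persistent(
            weighted[tps[a]], weighted[tps[b]],
            threshold_pct=config.over_threshold_pct, floor=floor,
        )
        kept = classed[~classed["floor_excluded"]]
        summary_rows.append(
            {
                "transition": label,
                **dataclasses.asdict(cc),
                # over-connections among floor-passing persistent edges
                "n_overconnections_floored": int(
                    (kept["change_class"] == "substantial-increase").sum()
                ),
                "baseline_floor": floor,
            }
        )
    _write("transition_summary.csv",
           lambda p: pd.DataFrame(summary_rows).to_csv(p, index=False))

    # edge-level sweep per transition
    sweep_frames = []
    net_primary: dict[str, pd.DataFrame] = {}
    for a, b in pairs:
        label = f"{tps[a]}-{tps[b]}"
        per_thr, report = edges.sensitivity_sweep(
            weighted[tps[a]], weighted[tps[b]],
            thresholds=config.sensitivity_thresholds, network_of=atlas.networks,
        )
        net_primary[label] = per_thr[float(config.over_threshold_pct)] \
            if float(config.over_threshold_pct) in per_thr else \
            edges.net_change_by_network(
                edges.classify_persistent(
                    weighted[tps[a]], weighted[tps[b]],
                    threshold_pct=config.over_threshold_pct,
                ),
                atlas.networks,
            )
        for thr, table in per_thr.items():
            _write(f"net_change_{label}_thr{thr:g}.csv",
                   lambda p, t=table: t.to_csv(p, index=False))
        report.insert(0, "transition", label)
        sweep_frames.append(report)
    sensitivity = pd.concat(sweep_frames, ignore_index=True)
    sensitivity["percentile_variant"] = config.percentile_variant
    _write("sensitivity_summary.csv", lambda p: sensitivity.to_csv(p, index=False))

    covariates = transitions.lesion_covariate_table(masks, counts)
    _write("lesion_covariates.csv", lambda p: covariates.to_csv(p, index=False))

    manifest = {
        "package": "disconnectome",
        "version": __version__,
        "config": config.to_dict(),
        "files": sorted(files + ["manifest.json"]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append("manifest.json")
    log.info("wrote %d files to %s", len(files), out)

    return {
        "cohort": cohort,
        "weighted": weighted,
        "binary": binary,
        "counts": counts,
        "edge_tables": edge_tables,
        "vulnerability": vuln,
        "sensitivity": sensitivity,
        "net_change_primary": net_primary,
        "covariates": covariates,
        "files": files,
        "output_dir": out,
    }


def clinical_sidecar(
    record: SubjectRecord,
    net_changes: dict[str, pd.DataFrame],
    motor_networks: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Descriptive side-by-side of somatomotor net changes and score deltas.

    ``net_changes`` maps a transition label (e.g. ``"S1-S2"``) to a
    net-change table from :func:`disconnectome.edges.net_change_by_network`.
    Score deltas are follow-up minus baseline for each recorded scale;
    missing scores produce explicit gaps (NaN), never errors. No statistics
    are computed - the table is for descriptive comparison only.
    """
    record.validate()
    if motor_networks is None:
        motor_networks = tuple(
            n for n in next(iter(net_changes.values()))["network"]
            if n.startswith("SomMot")
        ) if net_changes else ()
    rows = []
    tps = record.timepoints
    labels = [f"{tps[a]}-{tps[b]}" for a, b in transition_pairs(len(tps))]
    for label in labels:
        early, late = label.split("-")
        row: dict[str, object] = {"transition": label}
        table = net_changes.get(label)
        if table is not None:
            motor = table[table["network"].isin(motor_networks)]
            row["motor_net_change"] = int(motor["net"].sum()) if len(motor) else np.nan
        else:
            row["motor_net_change"] = np.nan
        for scale in SCALE_RANGES:
            per_tp = record.scores.get(scale, {})
            va, vb = per_tp.get(early), per_tp.get(late)
            row[f"delta_{scale}"] = (vb - va) if va is not None and vb is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
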