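"""Longitudinal edge-change classification across recovery transitions.

Every parcel pair gets exactly one category per transition: disconnection
(present -> absent), re-emerging (absent -> present), over-connection
(persistent with > 10% relative increase), persistent-other or absent-both.
Normalised counts divide by the number of existing connections at the
earlier session.
"""

from disconnectome import (
    CohortConfig, LesionSpec, classify_edges, count_changes, disconnection_fractions,
    generate_cohort, rsn_gain_loss, transition_pairs, weight_patient,
)
from disconnectome.engine import binarize

# a lesion that shifts and regrows produces losses as well as gains
config = CohortConfig(
    seed=11,
    lesion_specs=(
        LesionSpec((15.0, 16.0, 16.0), 6.0),
        LesionSpec((18.5, 17.0, 15.0), 4.5),
        LesionSpec((13.0, 15.0, 18.0), 5.5),
    ),
)
cohort = generate_cohort(config)
weighted = [
    weight_patient(cohort.healthy,
                   disconnection_fractions(cohort.streamlines, cohort.healthy, m))
    for m in cohort.masks
]

tps = cohort.config.timepoints
for a, b in transition_pairs(len(tps)):
    table = classify_edges(weighted[a], weighted[b], network_of=cohort.atlas.networks)
    counts = count_changes(table, binarize(weighted[a]))
    print(f"{tps[a]}->{tps[b]}: {counts.n_disconnections} disconnections, "
          f"{counts.n_reemerging} re-emerging, {counts.n_overconnections} "
          f"over-connections ({counts.pct_overconnections:.1f}% of "
          f"{counts.n_existing_baseline} baseline connections)")
    gl = rsn_gain_loss(table, cohort.atlas.networks)
    top = gl.sort_values("difference", ascending=False).iloc[0]
    print(f"   biggest net gainer: {top['network']} "
          f"(+{top['gained']} gained, -{top['lost']} lost)")
# each gained/lost edge is attributed to both endpoint networks
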