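"""Within- and between-network vulnerability per resting-state network.

Connectivity loss (healthy - weighted) is summed over intra-network parcel
pairs (within) and over pairs with exactly one endpoint in the network
(between), then normalised by the network's own healthy totals and
expressed as percentages.
"""

from disconnectome import (
    CohortConfig, connectivity_loss, disconnection_fractions, generate_cohort,
    network_vulnerability, weight_patient,
)

cohort = generate_cohort(CohortConfig(seed=7))

for mask in cohort.masks:
    frac = disconnection_fractions(cohort.streamlines, cohort.healthy, mask)
    weighted = weight_patient(cohort.healthy, frac)
    loss = connectivity_loss(cohort.healthy, weighted)
    table = network_vulnerability(loss, cohort.healthy, cohort.atlas.networks)
    worst = table.sort_values("within_pct", ascending=False).iloc[0]
    print(f"{mask.timepoint}: most vulnerable network {worst['network']} "
          f"(within {worst['within_pct']:.1f}%, between {worst['between_pct']:.1f}%)")
# with a nested shrinking lesion the vulnerability percentages can only
# decrease over the sessions (connectivity is progressively released)
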