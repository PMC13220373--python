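"""Lesion evolution metrics: volume, percent change, session overlap (DSC).

Percent change is reduction-positive: a shrinking lesion scores positive,
regrowth scores negative. DSC between consecutive sessions quantifies how
much of the discrete connectivity change is attributable to lesion-mask
evolution.
"""

from disconnectome import CohortConfig, dice_coefficient, generate_cohort, lesion_volume, percent_change
from disconnectome.lesions import format_percent

cohort = generate_cohort(CohortConfig(seed=7))
masks = cohort.masks
vols = [lesion_volume(m) for m in masks]

print("session  volume_mm3  pct_change_prev  pct_change_S1  dsc_prev")
for k, mask in enumerate(masks):
    pct_prev = format_percent(percent_change(vols[k - 1], vols[k])) if k else "-"
    pct_s1 = format_percent(percent_change(vols[0], vols[k])) if k else "-"
    dsc = f"{dice_coefficient(masks[k - 1], mask):.3f}" if k else "-"
    print(f"{mask.timepoint:>7}  {vols[k]:>10.0f}  {pct_prev:>15}  {pct_s1:>13}  {dsc:>8}")
# positive percent changes = volume reduction; DSC < 1 would indicate
# boundary shift between the sessions (here the masks are nested)
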