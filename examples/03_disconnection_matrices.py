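"""From lesion mask to patient-weighted connectome.

For each parcel pair the engine measures the fraction of its reference
streamlines intercepted by the lesion (disconnection fraction), keeps the
complement as the spared fraction, and scales the healthy streamline count:
weighted = healthy x spared. Binarizing at weight > 0 gives the existing
connections.
"""

import numpy as np

from disconnectome import (
    CohortConfig, binarize, disconnection_fractions, generate_cohort, weight_patient,
)
from disconnectome.core import triu_values

cohort = generate_cohort(CohortConfig(seed=7))
healthy = cohort.healthy

for mask in cohort.masks:
    frac = disconnection_fractions(cohort.streamlines, healthy, mask)
    weighted = weight_patient(healthy, frac)
    binary = binarize(weighted)
    disc = triu_values(frac.disconnection)
    n_healthy_edges = int((triu_values(healthy) > 0).sum())
    n_existing = int(triu_values(binary).sum())
    print(f"{mask.timepoint}: {int((disc > 0).sum())} pairs touched, "
          f"max disconnection fraction {disc.max():.2f}, "
          f"{n_existing}/{n_healthy_edges} healthy connections still existing")
# as the lesion shrinks, fewer pairs are touched and fully-intercepted
# connections re-emerge (weight returns above zero)
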