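"""Generate a synthetic three-session cohort with exact ground truth.

The cohort bundles a Voronoi parcellation with resting-state-network
labels, a healthy reference connectome of integer streamline counts, the
streamlines themselves, and a spherical lesion that shrinks across
sessions S1 -> S3. Ground-truth disconnection fractions come from an
exhaustive per-streamline voxel walk.
"""

import numpy as np

from disconnectome import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=7))
atlas = cohort.atlas

print(f"grid {cohort.config.grid_shape}, {atlas.n_parcels} parcels, "
      f"{len(set(atlas.networks.values()))} networks")
print(f"{len(cohort.streamlines)} streamlines; "
      f"healthy connectome holds {cohort.healthy.sum() // 2} of them")
nonzero = cohort.healthy[np.triu_indices_from(cohort.healthy, 1)]
print(f"minimum non-zero healthy weight: {nonzero[nonzero > 0].min()}")
for mask, vol in zip(cohort.masks, cohort.truth.lesion_volume_true):
    print(f"  {mask.timepoint}: lesion volume {vol:.0f} mm^3")
# volumes shrink because the lesion spheres are nested; every downstream
# stage can be checked against truth.disconnection_fraction_true exactly
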