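# Methods

## The model

`disconnectome` quantifies how a focal brain lesion disconnects a structural
network, and how that disconnection evolves over time, using an atlas-based
(indirect) approach: the patient contributes only binary lesion masks, and
all connectivity comes from a fixed healthy reference — a parcellation of the
brain into P regions (parcels), each assigned to one resting-state network
(RSN), and a reference set of streamlines whose two endpoints lie in a pair
of parcels. The healthy connectome `healthy(i,j)` is the end-to-end
streamline count between parcels i and j.

For a lesion mask at time t, a streamline is **intercepted** if any point of
its trajectory, densified to at most one-voxel spacing, falls inside a lesion
voxel. For every parcel pair,

    disconnection(i,j,t) = intercepted(i,j,t) / healthy(i,j)
    spared(i,j,t)        = 1 − disconnection(i,j,t)
    weighted(i,j,t)      = healthy(i,j) × spared(i,j,t)

`weighted` is the estimated post-lesion streamline count; thresholding it at
weight > 0 gives the binary connectome of existing connections. Pairs with no
healthy streamlines carry spared = 1 and weight = 0 at all times, keeping
patient matrices consistent with the reference. All matrices are symmetric
with zero diagonal; every edge statistic uses the strict upper triangle.

Because the weights are proportionally spared atlas counts, longitudinal
differences reflect release or capture of reference pathways by the moving
lesion boundary — not direct measurements of axonal remodelling. This is an
assumption of the whole approach, inherited by every downstream summary.

## Longitudinal analyses

With sessions S1..ST (three by default), transitions are the consecutive
pairs plus first-to-last: S1→S2 (early stage), S2→S3 (late stage), S1→S3
(overall). Per transition each edge receives exactly one category from the
zero/non-zero status of its weights:

| category | rule |
|---|---|
| disconnection | w_a > 0, w_b = 0 |
| re-emerging | w_a = 0, w_b > 0 |
| over-connection | both > 0 and relative change > threshold (strict) |
| persistent-other | both > 0, otherwise |
| absent-both | both = 0 |

Relative change is `(w_b − w_a)/w_a × 100`. Normalised counts divide each
category count by the number of existing connections at the earlier session.
RSN gains/losses attribute each re-emerging/disconnected edge to **both**
endpoint networks (an intra-network edge counts once for its network).

**Vulnerability.** Per-pair loss is `healthy − weighted`. For each network,
within-network loss sums over intra-network pairs and between-network loss
over pairs with exactly one endpoint inside; each is normalised by that
network's own healthy within/between total and expressed in percent. The
per-network denominator was a genuinely open choice ("total healthy
connectivity" admits a global reading); the per-network reading is adopted
because it is the only one under which a small, focally damaged network can
plausibly reach the ~40–60% vulnerability range, and it makes networks
comparable. The exact accounting identity
`Σ within + ½ Σ between = total loss` is asserted in tests. Networks with a
zero denominator report 0% and are flagged rather than dropped.

**Edge level.** Persistent edges are classed substantial-increase /
substantial-decrease when their relative change strictly exceeds ±threshold
(primary 10%). To prevent inflated percentages from near-zero baselines, a
floor equal to the 5th percentile (linear interpolation between order
statistics; the variant is recorded in output metadata) of all non-zero
baseline edge weights is applied per transition: edges with baseline
strictly below the floor are excluded; baseline exactly equal to the floor
is retained. Per-network net change = increases − decreases with the same
dual attribution; intra-network edges count once — whether such edges
should count twice is not determinable from the source analyses, so the
conservative once-per-network rule is used and verified by an exact
accounting identity. The sensitivity sweep repeats everything at 5/10/20%;
the floor depends only on the baseline matrix, so it is provably identical
across thresholds, and the stability report flags any network whose
net-change sign flips between thresholds (zeros are compatible with either
sign).

No hypothesis tests are computed anywhere: with single subjects followed
longitudinally, the analysis is descriptive, and the clinical-score sidecar
is an explicitly non-inferential side-by-side table.

## Lesion metrics

* volume = voxel count × voxel_size³ (binary masks, no partial volume);
* percent change = `(v_earlier − v_later)/v_earlier × 100`
  (reduction-positive); display values are rounded to one decimal with a
  trailing ".0" dropped, stored values are unrounded;
* DSC = `2|A∩B|/(|A|+|B|)`, with two empty masks scoring 1 (the 0/0 case is
  defined as perfect agreement, the common segmentation convention);
* NMI = `(H(A)+H(B))/H(A,B)` from a joint histogram with equal-width bins
  over the pooled intensity range — the bounded [1, 2] variant; constant
  images are rejected (zero entropy). NMI is provided as a standalone
  registration-QC metric only;
* lesion load intersects the mask with each parcel and rolls volumes up to
  networks.

## The synthetic cohort

No patient data ship with the package; the generator produces cohorts with
*exact* ground truth so every stage is testable end to end.

* **Atlas**: Voronoi cells of `n_parcels` seed voxels — non-empty by
  construction; networks assigned round-robin. Default 60 parcels in
  10 networks on a 32³ grid at 1 mm: the smallest scale at which network
  summaries are non-trivial while the exhaustive oracle stays instant. The
  study-scale shape (1035 parcels, 21 networks) is exercised in tests.
* **Streamlines**: quadratic Bezier curves between random points in two
  distinct parcels, stored pre-densified at ≤ 0.9-voxel spacing so no voxel
  is skipped by any intersection test. Default 600 streamlines: enough for
  count-1 edges to exist (giving matrices their minimum non-zero value of 1,
  as in real template-derived count matrices) yet instant to trace.
* **Lesions**: spheres (voxel center within radius of a possibly jittered
  center). Defaults are three nested shrinking spheres (radii 8, 5.5, 3) —
  the monotone-recovery reference condition; jittered centers emulate
  boundary shift (DSC < 1) and a dip-rise radius sequence emulates transient
  regrowth. Sphere + jitter is a stand-in for lesion morphology, not a claim
  about real lesions: real lesions are irregular, non-convex, and evolve
  anisotropically, so tests passing here show algorithmic correctness, not
  anatomical realism. Likewise absent from the generator: registration
  error, anatomically plausible fiber geometry, and any diffusion signal.
* **Ground truth**: disconnection fractions by an exhaustive per-streamline,
  per-point membership walk written independently of the engine; volumes are
  analytic (voxel count × voxel volume); edge categories recomputed from the
  true fractions with plain loops.
* **Seeding**: one master seed; atlas/streamlines/lesions each consume an
  independently spawned child stream, so adding a stage never perturbs
  earlier ones, and identical config ⇒ bit-identical outputs.

## Numerical choices

* Point-to-voxel membership is `floor` of voxel-frame coordinates; affines
  exist only at NIfTI I/O. Points exactly on the far grid face belong to the
  last voxel.
* Interception needs a single densified point inside the lesion — the most
  sensitive reading; no minimum overlap length.
* Because generated polylines are already denser than the engine's 1-voxel
  densification step, the engine's point set equals the stored points and
  engine output equals the exhaustive oracle exactly (asserted, not
  approximately, in tests).
* Strict inequalities at thresholds: exactly +10% is persistent-other /
  stable; baseline exactly at the floor is retained.
* Degenerate inputs raise typed errors rather than returning NaN: zero
  baseline volume (percent change), all-zero baseline connectome (floor),
  constant image (NMI), zero existing baseline connections (normalised
  counts).
* Pipeline NIfTI outputs are uncompressed and the manifest carries no
  timestamps, so a rerun with the same config reproduces the bundle
  byte-for-byte.

## Problem sizes

Tests and the acceptance script run cohorts of 18³–48³ voxels, 15–60
parcels and 150–600 streamlines — sizes chosen so the exhaustive oracle can
re-derive every quantity within seconds while still exercising every code
path (count-1 edges, fully intercepted pairs, dual-network edges, all five
categories). The analysis code itself is vectorised and handles
study-scale matrices (1035 parcels ≈ 535k edges) without modification.

## Known limitations

* Indirect connectivity only: no tractography, no tract-level (named
  bundle) summaries, no probabilistic disconnection maps.
* No graph-theory metrics (efficiency, modularity, hubness) and no
  statistical inference — both deliberately out of scope.
* The reduction-positive percent-change convention and the display rounding
  reproduce clinical lesion-evolution tables; table cells derived
  elsewhere from truncated or unrounded source values can differ from
  recomputation by ≤ 0.1 percentage points, and the package reports
  standard half-even rounding instead of matching such cells.
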