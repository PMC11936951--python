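# Methods

`ecgloc` localizes and labels body-surface-potential-mapping (BSPM) ECG
electrodes in 3D from a sequence of RGB-D views of the torso.  This note
documents the models, algorithms, parameter choices and known limitations;
the README covers usage.

## Problem setting

BSPM records ECG from on the order of a hundred electrodes arranged in
color-coded strips (four classes A–D; 5 mm electrode diameter; 30 mm
spacing between neighbors within a strip).  Downstream analyses —
in particular electrocardiographic imaging (ECGI), the inverse
reconstruction of cardiac surface potentials — need each electrode's 3D
position *and* its acquisition-channel identity.  The pipeline recovers both
from multi-view RGB-D imagery plus per-view electrode detections (bounding
box + color class), with no markers and no manual interaction.

## Pipeline stages

### Back-projection (`geometry`)

Each valid-depth pixel (u, v) with depth d maps through the pinhole model to
`((u-cx) d/fx, (v-cy) d/fy, d)` in the view's camera frame (x right, y
down, z optical axis; depth in millimeters, 0 = invalid).  Projection and
back-projection are exact inverses at pixel centers.  The on-disk depth
format is 16-bit PNG in integer millimeters, which adds up to 0.5 mm
quantization noise on disk round-trips; in-memory frames carry float
millimeters.

### Denoising (`geometry.denoise_cloud`)

Raw clouds include the environment.  DBSCAN (scikit-learn) clusters the
cloud and exactly the largest cluster is kept, noise and smaller clusters
dropped.  Defaults `eps = 20 mm`, `min_points = 10` suit clouds whose
point spacing is a few millimeters (the pipeline's default pixel stride of 2
gives ~1.6 mm spacing at 60 cm standoff); both are exposed.  Ties in
cluster size break toward the lowest cluster label, making the choice
deterministic.

### Torso reconstruction (`registration.reconstruct_torso`)

Consecutive views (~10° apart) are aligned pairwise and compositions chain
every view into the frame of view 0.  Per pair, two ICP stages run on
voxel-thinned copies (`voxel_size`, default 4 mm): point-to-plane first
(normals from 30-nearest-neighbor PCA planes, oriented toward the camera),
then point-to-point refinement.  Correspondences beyond a distance cap are
excluded (50 mm plane stage / 20 mm point stage), and each iteration
additionally discards the worst-residual 20 % (`trim_fraction`): with
partial overlap, points visible in only one view otherwise drag the minimum
off by ~0.5°/5 mm per pair.  Updates are step-halved until the trimmed
objective is non-increasing, so the recorded objective decreases
monotonically by construction; iteration stops at a relative improvement
below `convergence_tol` (1e-6) or `max_iterations` (50).

Two measured failure modes of textbook ICP on smooth, feature-poor surfaces
shaped this design:

* **Partial-overlap bias** — handled by trimming, as above.
* **Sliding degeneracy of point-to-point** — on a smooth torso the
  point-to-point objective is nearly flat along within-surface sliding
  modes and can *genuinely prefer* poses millimeters from the truth (its
  RMS drops ~14 % while moving 4 mm, by overlapping the two views'
  sampling-density footprints).  The refinement stage is therefore
  verification-gated: its pose is accepted only if it does not degrade the
  pair's point-to-plane consistency by more than 5 %; otherwise the plane
  pose stands.  On feature-rich clouds the refinement passes the gate and
  contributes; on the phantom it is usually rejected, and chained drift
  stays below ~0.2 mm over 11 pairs.

No global pose-graph optimization or loop closure is attempted; the views
span ~110°, so the chain is short and drift stays sub-millimeter.

### Electrode extraction and fusion (`detection`)

Per detection, all valid-depth pixels inside the bounding box are
back-projected and averaged (arithmetic mean); boxes with no valid depth are
dropped and reported.  Per-view centers are mapped into the frame of view 0
and fused per class by single linkage at `merge_radius = 14 mm` — below
half the 30 mm strip spacing, so adjacent electrodes cannot merge, while
per-view scatter (well under 2 mm) always links.  A fused electrode's
position is the exact mean of its group; its `support` counts contributing
views.  Grouping never crosses classes, and a merge radius ≥ half the
nominal spacing is rejected as a configuration error.

The bundled reference detector (connected components of class-colored
pixels, ≥ 20 px, scikit-image) only handles synthetic renders; real imagery
is expected to come with external detections (JSON-lines), e.g. from a
trained object detector.

### Channel labeling (`labeling`)

Channels are assigned by growing strips in class order A→D:

1. **Seeding (first strip of each class).** The two class electrodes whose
   projections in the seed view (view 0) lie closest to pixel (0,0),
   ordered by that distance; visibility is tested against the seed view's
   depth raster (projected depth within 10 mm).  This presumes the
   nearest-to-origin pair is adjacent within one strip — true by
   construction for the synthetic layouts, and an explicit assumption for
   real strip sets.
2. **Growth.** From the last two electrodes, candidates must lie within
   35 mm Euclidean distance *and* 15 mm along x of the current electrode;
   among them the one minimizing perpendicular distance to the line through
   the previous two wins, so strips extend collinearly.  No candidate ⇒
   strip ends.
3. **Subsequent strips.** Seeded from the unlabeled same-class strip
   *endpoint* nearest the previous strip's start, paired with its gated
   nearest neighbor.  An endpoint is an electrode with at most one gated
   unlabeled neighbor; seeding from an interior electrode (possible when a
   tilted strip leans toward its predecessor) would split the strip and
   reverse part of the traversal.
4. Electrodes with no gated partner become singleton strips and are
   reported in a completeness warning.

All tie-breaks are lexicographic (smaller v then u in the image; smaller
x, y, z in 3D), making the labeling deterministic and invariant to input
ordering.  The x-gate presumes strips run roughly vertically in a frame
whose x-axis is horizontal — the camera frames of a level rig satisfy this.

### Scale calibration and error metrics (`evaluation`)

A reconstruction from an uncalibrated source (monocular video) is rescaled
by `known_spacing / mean_adjacent_spacing`, where the mean is taken over
consecutive-channel pairs within strips (all unordered within-strip pairs
would average far above the nominal spacing, so "adjacent pairs" is the
reading consistent with reported ~30 mm means).  The operation is
idempotent by construction.

Localization error against a reference map matches electrodes **by channel
label** (mislabeling shows up as large error rather than being absorbed),
aligns the maps with the closed-form Umeyama least-squares estimator (rigid
by default; similarity on request; reflection corrected by flipping the
smallest singular vector), then reports per-electrode 3D Euclidean
distances, per-axis absolute differences, means ± SD (n−1 denominator), and
a breakdown over torso regions.  Regions are an artifact convention:
electrodes within ±60° azimuth of the anterior axis are "front", split at
the map's median height into chest/abdomen; the rest are "sides".

## Synthetic phantom (`phantom`)

The simulator emulates a rigid torso phantom carrying the 118-channel strip
set, imaged by a depth camera from 12 poses 10° apart at 600 mm from the
torso axis (a centered ±55° fan; 12 stops at 10° cannot literally span
180°).

* **Surface**: elliptic cross-section (half-width 160 mm, half-depth
  110 mm — adult-male torso scale) extruded over y ∈ [−225, 100] mm with a
  quarter-ellipse shoulder dome of height 125 mm.  The dome matters: a pure
  elliptic cylinder is translation-symmetric along its axis and would make
  view-to-view registration ill-posed.
* **Electrodes**: 15 vertical strips, classes interleaved A,B,C,D around
  the front and sides (azimuth parameter −70°…70°, tops at y = 95 mm).
  A/B/C have 4 strips × 8; D has 2 × 8 + 1 × 6 (= 118 total).  Within-strip
  chord spacing is exactly 30 mm (solved numerically on the meridian).
  Interleaving keeps same-class strips ~40° ≈ 80+ mm apart — far beyond the
  labeling gates, so strips cannot be confused — and places one strip of
  every class in view 0 for seeding.  The real BioSemi arrangement is
  undocumented; this layout is a stand-in, not the clinical geometry.
* **Rendering**: analytic ray casting (closed-form elliptic-cylinder
  intersection; marching + bisection on the dome), no mesh rasterizer.
  640×480, fx = fy = 600 px.  Visible (front-facing, unoccluded) electrode
  sites are painted as 5 mm class-colored disks; tight boxes around disks of
  ≥ 6 px become ground-truth detections (smaller silhouette specks are
  below any detector's working range and their boxes average depth across
  the steep silhouette).
* **Noise**: Gaussian depth noise (mm), Gaussian bounding-box jitter (px),
  per-detection dropout; one seeded generator per view
  (`SeedSequence([seed, view])`) makes renders bit-reproducible.
* **Respiration**: sinusoidal site displacement
  `0.5 · amplitude · profile(region) · sin(2π·phase)`, dominantly along z;
  default peak-to-peak 9.66 mm (z) / 1.45 mm (x, y) follows the largest
  marker excursion tracked on a free-breathing subject, with a mid-chest
  dominant spatial profile (chest 1.0, abdomen 0.6, sides 0.4 — a modeling
  choice).  The phantom is a rigid model, so scenes default to no
  respiration; displaced sites are re-projected onto the (static) surface,
  so the normal-direction component of breathing motion is not expressed in
  the rendered depth — a stated simplification.

**What a green synthetic test does not establish:** robustness to real
sensor noise statistics, lighting/color variation (the reference detector
assumes flat saturated disks), soft-tissue deformation, non-convex torso
geometry, or detector misclassification.  The phantom validates geometry and
logic, not perception.

## Numerical choices

* Rotations are re-projected to SO(3) via SVD after composition; transform
  constructors validate orthonormality at 1e-8.
* Umeyama rejects configurations with rank < 2 (second singular value below
  1e-12 of the first).
* Surface-distance validation uses exact 2D point-to-ellipse distance
  (vectorized bisection) in the point's own cross-section; on the dome this
  is an approximation whose error is second order in the distance.
* Voxel downsampling averages points per cubic cell with deterministic
  ordering; DBSCAN, KD-trees and connected components come from
  scikit-learn/SciPy.
* Pipeline defaults: pixel stride 2 for the clouds fed to clustering and
  ICP (full resolution is always used for electrode extraction), seed view
  0 for labeling.

## Known limitations

* The labeling seed rule inherits the nearest-to-(0,0) convention; torsos
  or camera rigs where the two nearest same-class electrodes are not strip
  neighbors in the seed view will mis-seed.  The rule is isolated behind
  one function for replacement.
* Sequential pairwise chaining has no loop closure; very long or full-circle
  trajectories would accumulate drift.
* The reference detector is deliberately naive and must not be used on real
  photographs.
* Disk I/O quantizes depth to integer millimeters; workflows needing
  sub-millimeter fidelity should keep frames in memory.
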