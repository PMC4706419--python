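# Methods

## The model

`whiskscape` simulates the contact patterns that a rat's macrovibrissal array
makes with a flat surface as a function of head pose.  The model has three
layers:

1. **Array morphology.**  62 whiskers (31 per mystacial pad) arranged in rows
   A (dorsal) to E (ventral) and columns Greek (caudal) to 6 (rostral).  Arc
   lengths, resting azimuths (`theta_rest`), full-retraction azimuths and
   per-row resting elevations are published values and are hard-coded in
   `whiskscape.tables`.  Each whisker is a planar circular arc discretized at
   100 nodes evenly spaced in arc length.  The left array is the exact mirror
   image of the right across the midsagittal plane — bitwise, not just to
   rounding — which makes the left/right reflection symmetry of every
   downstream result an exact invariant rather than a numerical one.

2. **Whisking kinematics.**  Azimuth θ advances in 0.1°/step increments from
   rest (default amplitude 60°, configurable, including full-retraction starts
   and per-column large-protraction amplitudes).  Elevation and roll are
   affine in the protraction angle dθ with row-specific coefficients
   (e.g. row A: ϕ = 56 + 0.12·dθ, ζ = ζ₀ − 0.76·dθ).  A posed whisker is the
   rigid motion `basepoint + R_z(θ−90°)·R_y(−ϕ)·R_x(ζ)·curve`: roll about the
   emergence axis first, then elevation, then azimuth, so that θ and ϕ read
   back exactly as the azimuth/elevation of the base tangent regardless of ζ.

3. **Contact sweep.**  The wall is an infinite half-space expressed in head
   coordinates: a node `p` has crossed it iff `p·n ≥ d`.  The head rotation is
   composed as extrinsic yaw about the world vertical, then pitch about the
   interaural axis (the alternative order is a config flag; all single-axis
   slices are order-independent).  The first step at which any node crosses
   gives the contact; its class is *resting* (contact already at step 0),
   *whisking* (first contact at a later step) or *none*.  θ_impact is the
   whisker's base-tangent azimuth at the contact step.  No post-contact
   bending is simulated.

The standard pose grid is distance 0–60 mm (1 mm), yaw and pitch −90°…+90°
(5°): 61 × 37 × 37 = 83,509 poses.

### The projection factorization

Node projections onto the wall normal depend only on (yaw, pitch).  For each
of the 37 × 37 orientations the per-(whisker, step) maximum node projection is
computed once, its running maximum over steps is monotone, and all 61
distances are resolved by thresholding that running maximum.  This is an
optimization only: `first_contact` is the reference per-(whisker, pose) path,
and the grid simulation is tested to agree with it exactly, including the
contact-node tie-break (first crossing step, lowest crossing node index).
An earlier implementation resolved the thresholds through a single
`searchsorted` over per-whisker offset blocks; that was abandoned because the
large additive offsets cost ~4 µunits of float64 resolution — enough to flip
one borderline contact in 83k poses and break exact left/right symmetry.
The full grid runs in under a minute on one CPU.

## Synthetic morphology: what is invented and why

The per-whisker basepoint coordinates, resting roll ζ₀ and intrinsic
curvature are not published in the source tables; the package generates them
from a small config-exposed parameter set (`MorphologyParams`):

- **Basepoints** sit on a laterally facing ellipsoidal pad patch, rows spaced
  2.5 mm in z, columns 2.5 mm in y, Greek column offset 1.25 mm ventrally.
  The pad center defaults to (±8, −9, 0) mm from the nostril midpoint, which
  puts the columns at y ∈ [−16.5, −1.5] mm.  The rostral position was chosen
  on anatomical grounds: the rostral microcolumns of the rat pad lie just
  caudal of the nostrils, and with the published lengths, rest angles and
  elevation couplings the maximum frontal sweep of any whisker tip is
  ~21–28 mm beyond its basepoint, so a pad centered 15 mm caudal of the nose
  could never reproduce the observed ~16 mm guaranteed frontal coverage.
- **Resting roll** ζ₀ defaults to 0° for every whisker (per-whisker
  overridable).  The published sensitivity result (±20% perturbations barely
  move θ_impact) and the roll-removal manipulation justify a neutral default.
- **Intrinsic curvature** defaults to a 35° circular arc for all whiskers,
  oriented concave-forward at rest (the curvature plane contains the
  protraction direction).  A single arc-angle parameter supports the
  doubled-curvature and straight-whisker manipulations cleanly.

### What the synthetic morphology does and does not reproduce

With these defaults the package reproduces the coarse spatial structure of
the published study: guaranteed-contact distance 17 mm (published 16),
unreachable fraction at 60 mm 29.6% (published 25.7%), column-wise maximum
whisking reach falling from ~39 mm (Greek) to 10 mm (column 6), exterior-row
resting-contact asymmetry in pitch, the interior-row robustness ordering
under pitch uncertainty, and the sign/ordering structure of the nL−nR yaw
cue.  Known deviations, all traceable to the invented layout (see
`scripts/morphology_sweep.py`):

- **Configuration uniqueness** is lower than published: 21.9% at 5°
  tolerance (published 36.9%) and 58.8% among poses with ≥3 whisking
  contacts (published 70.5%), under the pairwise reading of the tolerance
  (below).  The synthetic array produces whisking contacts in fewer poses
  (27,784 vs 35,404 with ≥3 whisking), mostly because the flat-patch layout
  with neutral roll gives the exterior rows steeply inclined sweeps that
  convert would-be whisking contacts into resting contacts or misses.
  Notably, the layout sweep keeps the pairwise fraction within 19–24% across
  every variant tried while the binned reading lands at 34.4% on the default
  layout, which suggests the published percentages were computed over
  tolerance-binned angles.
- **Fixed-pose distance correlation** is ≥ 0.999 for most whiskers but dips
  to 0.983 for C4, whose whisking band at (pitch 0, yaw 0) spans only 12 grid
  distances and ends in the steep near-saturation rise of θ_impact(d).
- The interior-row maximum-reach peak sits at steeper negative pitches
  (≈ −70°) than in the real array (between 0 and −35°): with ζ₀ = 0 the
  B-row's rising elevation (+25°…+43°) dominates its reach direction.
- Near-wall poses (d < 5 mm) are *more* unique than far poses in this
  morphology, not less: the real array wraps the snout so that very near
  walls saturate nearly all whiskers into resting contact, while the flat
  patch keeps near-wall class patterns diverse.

## Analyses

- **Reachability** counts resting-plus-whisking contacts per pose; the
  guaranteed-contact distance is the largest grid distance below which every
  pose is reachable.
- **Blind spot**: voxel occupancy (default 1 mm voxels; tests use 2 mm) of
  all node positions over the sweep inside a probe box x ∈ [−25, 25],
  y ∈ [0, 40], z ∈ [−25, 25] mm; the blind set is the unoccupied remainder,
  labelled by connected components.  Occupancy uses node points, not swept
  segments; with 0.1° steps the point cloud is far denser than the voxels.
- **Yaw cue**: nL − nR per pose, with an ordinary least-squares line per
  distance, pitches pooled (matching the overlaid-pitch presentation of the
  published figure).
- **Correlations**: Pearson r between distance and θ_impact over whisking
  contacts only.  Per-whisker at a fixed pose; row-pooled under pose
  uncertainty, where uncertainty u pools poses within a window of total
  width u centered on 0 (u = 180° spans the whole grid axis).  Pools with
  fewer than 3 points or zero variance give NaN, never an imputed 0.
- **Uniqueness**: two poses are indistinguishable iff their 62-way
  contact-class patterns are identical and their whisking θ_impact values
  agree within the tolerance.  The default compares paired angles directly
  (strict |Δθ| < tol on every whisking whisker, Chebyshev
  fixed-radius search within class-pattern buckets, oracle-tested against an
  O(n²) sweep); `method="binned"` instead discretizes angles into
  tolerance-wide bins, which is how a database lookup over rounded angles
  behaves.  The two readings bracket the published percentages (binned:
  34.4% at 5°; pairwise: 21.9%); the source does not state which was used.
- **Group averages**: θ_impact averaged within rows or columns at yaw 0 over
  whisking contacts only; groups whose members only rest are flagged rather
  than averaged.

## Sensitivity analysis

Six parameter groups vary independently per whisker: length (uniform, up to
20% shorter), resting elevation and roll (uniform ±20%), the elevation and
roll coefficients (truncated normal, σ = bound/2, support ±bound;
`coeff_mode="uniform"` switches to uniform-on-bounds), and basepoint position
(uniform direction, magnitude up to 15% of the nearest-neighbor distance).
Draws are made for the right pad and mirrored, preserving the reflection
invariant.  The published description derives 42 configurations from a
13-distance × 7-pitch grid; that grid actually contains 91 poses, and the
grid as stated is what runs here (the discrepancy is noted, not resolved).
The desk-scale default is 100 repetitions (~30 s); 1,000 matches the source
study.

Two dispersion statistics are reported per whisker, both over whisking
contacts only.  The *pooled* standard deviation (across every configuration
and repetition) is dominated by the pose sweep itself: with the perturbations
switched off entirely it is already 12–18° for most whiskers, because a
whisker's θ_impact legitimately spans tens of degrees across distances and
pitches.  The *within-configuration* standard deviation (variance across
repetitions within each pose, pooled over poses) isolates the dispersion that
parameter variation adds, is zero by construction for null perturbations, and
is the statistic the robustness claim is tested on: with default
perturbations all 31 whiskers stay below 10°.

## Numerical choices and degenerate inputs

- Angles are degrees in every interface, radians only inside rotation code;
  distances are mm.  Contact testing uses ≥ (touching counts); at 0.1° steps
  the strict/non-strict difference is below grid resolution.
- Step counts: `floor(amplitude / step + 1e-9) + 1`, including the start
  position (601 for 60°/0.1°).
- Whiskers with zero or one whisking contact: correlations NaN, sensitivity
  statistics computed only over contacting trials, groups with no whisking
  member flagged.
- `guaranteed_contact_distance` warns and returns the grid edge if every
  distance is reachable, and warns and returns 0 if even d = 0 has
  unreachable poses.
- The curved-surface check replaces the wall by a vertical cylinder tangent
  to it at the foot of the head-wall perpendicular, curving away from the
  rat.  The published "< 0.1 deg/mm" flatness bound does not name its
  denominator; it is read here as dθ_impact/dR, the sensitivity of the impact
  angle to the radius of curvature near R = 140 mm, estimated by finite
  differences between radii (the alternative reading — degrees per mm of
  surface sag — is inconsistent with the steep published distance–θ_impact
  slopes, which are several deg/mm).

## Limitations

No whisker bending after contact, no contact forces, no whisk-cycle timing,
no bilateral asynchrony, no tapered-beam mechanics, and no surfaces more
curved than the 140 mm cylinder check.  The synthetic basepoint layout is an
approximation; every layout number is exposed in `MorphologyParams`, and
conclusions that depend on fine morphometry (uniqueness percentages, exact
peak-pitch locations) should be read with the deviations listed above in
mind.
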