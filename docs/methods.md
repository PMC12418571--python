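# Methods

## Model

Post-hoc motion correction yields, per volume, six rigid-body
parameters: translations `tx, ty, tz` (mm) and rotations
`rx ("pitch"), ry ("roll"), rz ("yaw")` (radians), relative to a
reference volume. `vvoqc` converts each 6-vector to the homogeneous
transform

```
T(p) = Trans(tx, ty, tz) · Rx(rx) · Ry(ry) · Rz(rz)
```

with right-handed, counterclockwise-positive rotation matrices about
the **world origin of the parameter frame** — rotations are applied
where realignment estimated them, not about any voxel center, which
is exactly why distant voxels move farther under the same rotation.
Motion of volume *t* relative to a reference *r* is
`T_t · T_r⁻¹`; the first row of the parameter file is used as given
(it is the reference's own parameters, typically zeros) and never
forced to zero.

### Overlap by half-space clipping

A voxel is an axis-aligned cuboid: the intersection of six
half-spaces, each given by a point on the face and an inward unit
normal. The overlap of the moved voxel with its unmoved self is
computed by clipping the moved cuboid against the six planes in
sequence. Each face polygon of the (convex) intermediate body is
clipped edge-by-edge: vertices on the kept side survive, an edge
crossing the plane contributes the point found by linear
interpolation `p = a + t(b−a)`, `t = d_a/(d_a−d_b)` on the signed
distances, and the cut opening is closed with a planar cap face (the
intersection points ordered by angle in the cutting plane — valid
because every section of a convex body is convex). The remnant of a
convex body under half-space cuts is convex, so its volume equals the
volume of the convex hull of its vertices; we evaluate it with
Qhull's hull tetrahedralization (`scipy.spatial.ConvexHull`), which is
the same sum-of-tetrahedra computation a Delaunay decomposition
yields for a convex point set. The overlap fraction is remnant
volume / (dx·dy·dz), clamped to [0, 1] against round-off.

An independent **Monte-Carlo oracle** (`mc_overlap_oracle`) samples
points uniformly inside the moved cuboid and counts the fraction
landing in the reference cuboid (SE ≈ √(p(1−p)/n)); the test suite
holds the clipping path to within 3 SE of this estimator over 200
seeded random transforms and never substitutes one for the other.

### Numerical choices

- **On-plane tolerance 1e-9 mm**: vertices within tolerance of a
  cutting plane are classified as kept (inclusive), so a face shared
  between the moved and reference cuboid loses no sliver; the same
  tolerance deduplicates vertices.
- **Degenerate remnants** (empty set, point, segment, planar polygon)
  have volume 0 and are returned silently — they are legitimate "no
  3-D overlap" outcomes, not errors.
- **Identity fast path**: a transform equal to the identity within
  1e-14 returns overlap exactly 1, so a still timepoint reports
  exactly 100 %.
- Clipping with a half-space that contains the whole body returns it
  unchanged (no interpolation noise accumulates over the six planes).

## The VVO measures

For each timepoint the overlap is evaluated at **six representative
voxels** at radius 65 mm (default) from the origin along ±x (R/L),
±y (A/P), ±z (S/I) in RAS axes — motion effects are spatially
heterogeneous, and 65 mm is the empirical average cortical distance
in adults. The per-timepoint summary is the **median of the six**
(mean of the 3rd/4th order statistics), a robust choice given no
location is privileged a priori. `TD_VVO` uses `T_t·T_1⁻¹`
(drift-sensitive), `STS_VVO` uses `T_t·T_{t−1}⁻¹` (spike-sensitive);
both are percentages, and the first timepoint is 100 by convention.
`compute_vvo` accepts arbitrary user centers (e.g. atlas region
centroids) in place of the six defaults.

Applying the relative transform to the axis-aligned reference cuboid
and clipping against its own planes is equivalent, by rigid volume
preservation, to intersecting the two moved cuboids — one clipping
path serves both measures (the forward/inverse symmetry is asserted
to 1e-9 in the tests).

### Conventional TD / STS

The conventional displacement series is the median Euclidean
displacement of the same six representative points, which reduces to
plain 3-D Pythagoras for pure translations and to the chord length
`2r·sin(θ/2)` for pure rotations. An alternative aggregator
(root-sum-square of the three translations and the three arc lengths
`θ·r`) is available via `aggregate="rss"` for comparability with
simpler summary formulas; the median-of-points form is the default
because it is internally consistent with the VVO probe locations.

### Out-of-plane decomposition

The displaced (non-overlapping) volume is split by the acquisition
slab: the moved cuboid's volume beyond the two reference faces
perpendicular to the through-plane axis (axial→z, coronal→y,
sagittal→x) is out-of-plane; the rest of the non-overlap is in-plane.
The reported proportion pools numerator and denominator over the six
probe centers before dividing — per-center ratios are ill-conditioned
when a probe barely moves, and the pooled form degrades gracefully;
the unpooled per-center ratios are emitted alongside for inspection.
Since the acquisition plane is fixed for a run, the reference is
always the first volume, and a timepoint with no displaced volume at
all is flagged undefined rather than given an arbitrary value. Axes
are assumed cardinal (non-oblique acquisitions aligned with the
parameter frame).

## Calibration and quality labels

Overlap and millimetre displacement are linked per session by
`STS_VVO = 100 − a·STS`, with the intercept pinned by the physical
constraint that zero motion is 100 % overlap. The least-squares
solution under that constraint is regression through the origin on
the deficit: `a = Σ xᵢ(100−yᵢ) / Σ xᵢ²`, over pairs with STS inside
the clinically realistic 0–1.5 mm window (inclusive; windowing is on
STS only). A session yields a slope only if **more than 25 %** of its
datapoints survive the window (and the kept displacements are not all
zero); the across-session summary is the mean slope of included
sessions. The lookup table writes `100 − a·STS` on a 0.05 mm grid,
rounded **half-away-from-zero at two decimals** and clamped at 0 —
this rounding reproduces the reference table exactly at
`a = 43.2422`.

Quality labels on STS_VVO use inclusive-upward boundaries
(≥90 very_high, ≥80 high, ≥55 potentially_acceptable, else
questionable; 35 % is the very-lenient marker). The equality case is
a package decision — the thresholds were stated as "above"/"below"
without defining ties. The censoring regressor flags volumes with
median overlap **strictly below** the threshold and emits both the
0/1 indicator and the one-column-per-flagged-volume spike matrix.
Association with conventional measures is reported as a Spearman rank
correlation (Kendall selectable), expected negative for
motion-containing series, and flagged undefined for constant input.

## Synthetic motion generator

Three generators make every stage testable without any dataset:

- `pure_shift_series`: a zero reference volume followed by single-axis
  shifts of 0.5–3 mm in 0.5 mm steps — the ground-truth grid whose
  overlap is known in closed form (`Π max(0, 1−|sᵢ|/dᵢ)`).
- `random_series`: per-axis Gaussian random-walk drift
  (default sd 0.02 mm/volume) plus Bernoulli motion spikes
  (rate 0.05, transient translation offsets of sd 0.5 mm) and
  random-walk rotations (sd 0.002 rad/volume). The defaults land mean
  STS near 0.2 mm for a 200-volume session, within the 0.07–0.26 mm
  range typical of adult resting-state and pediatric task cohorts.
  Spikes are transient rather than cumulative because scan-to-scan
  metrics exist precisely to catch motion that reverses.
- `calibration_session`: STS drawn from a half-normal (scale 0.3 mm)
  truncated to 0–1.5 mm, STS_VVO from the known line plus Gaussian
  noise (sd 2 %), clamped to [0, 100].

What the generator does *not* emulate: task-locked motion,
physiological noise, spin-history effects, intra-volume (slice-wise)
motion, oblique acquisitions, or realistic autocorrelation between
spikes. Passing tests therefore demonstrate the geometry, the
bookkeeping, and estimator recovery under known generative models —
not empirical claims about any real cohort.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| radius | 65 mm | probe-voxel distance from origin (adult cortical distance) |
| size grid | 4, 3.5, 3, 2.5, 2, 1.5, 1, 0.5 mm | isotropic voxel-size sweep |
| calibration window | 0–1.5 mm | STS range entering the fit and lookup |
| survival rule | > 25 % | minimum in-window fraction for a session slope |
| lookup step | 0.05 mm | lookup-table granularity |
| quality cutoffs | 90 / 80 / 55 (35) % | very strict / strict / lenient (very lenient) |
| censor threshold | 55 % | default scrubbing floor on median STS_VVO |

Validation runs use 200 random transforms against the 10⁶-sample
Monte-Carlo oracle and 50 synthetic calibration sessions of 300
datapoints; a 60-volume session is used for end-to-end examples.
These sizes give sub-minute suites while keeping the Monte-Carlo
standard error near 5·10⁻⁴ and the slope-recovery standard error
well under the ±1 acceptance band.

## Known limitations

- Only cuboid-versus-its-own-moved-copy intersection is implemented —
  not general polytope–polytope intersection; that is all the overlap
  measures require.
- Effective (smoothness-based) resolution is accepted as
  user-supplied dimensions (`label="effective"`); estimating it from
  GLM residuals is out of scope, and the acquired voxel size is the
  recommended reference.
- Rotation conventions differ between software ecosystems; inputs are
  harmonized to the internal order (translations first, radians,
  `T·Rx·Ry·Rz`) but parameter files produced by exotic pipelines
  should be checked against the dialect table in `io_motion`.
- Floating-point, not exact rational, arithmetic: overlap values are
  reliable to well below 1e-9 of the voxel volume, which the
  tolerances above reflect.
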