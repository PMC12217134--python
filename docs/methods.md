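# Methods

## Scope and model

`rodentmorph` measures the morphometry of rodent knee soft tissues from
segmented 3D surfaces: the cross-sectional area (CSA) of the four primary
ligaments (ACL, PCL, MCL, LCL), the regional widths and heights of the
medial and lateral menisci, and the tibial-plateau footprint area used to
normalize ligament size across species. It also implements the statistics
layer such a study needs — rank-based omnibus and post hoc tests, aligned
rank transform (ART) factorial tests, and method-agreement analysis
(Bland–Altman, ICC).

Inputs are triangle surface meshes in millimetres (STL), as exported by
segmentation software from high-field MRI scans (0.1 mm isotropic voxels
for rat, 0.05 mm for mouse), or binary label volumes from which surfaces
are generated by Gaussian smoothing (sigma in voxels, default 1.0) and
0.5-level marching cubes. The iso-surface algorithm used by commercial
segmentation packages is not published; level-0.5 marching cubes is our
stand-in for it. With `sigma = 0` the exact voxel staircase boundary is
returned instead, so that a one-voxel mask is a cube and smoothing
demonstrably reduces surface area.

## Ligament CSA

1. The mesh's unique vertices form a surface point cloud.
2. The cloud is centered and rotated so its longitudinal axis lies on +z.
   The axis is the first principal component of the vertex cloud; the
   method is only accepted when the dominant principal extent is at least
   1.2x the second (otherwise there is no meaningful long axis and a
   degenerate-axis error is raised). The sign of +z is fixed by requiring
   nonnegative skewness of the aligned z-coordinates, making the frame
   deterministic.
3. The cloud is cut into half-open slabs `[z_lo, z_lo + dz)` from the
   minimum z, with `dz` defaulting to the species voxel size (0.1 mm rat,
   0.05 mm mouse). A final partial slab is kept when it still holds at
   least 3 points. Slabs with fewer than 3 points get area 0 and a logged
   warning.
4. Each slab is flattened orthographically along z (no obliquity
   correction) and its CSA computed by one of two methods:
   - `hull` (default): area of the 2D convex hull of the slab's points.
   - `plane_intersection`: enclosed area of the loops where the aligned
     mesh crosses the slab's mid-plane. This is exact for any
     cross-section shape and serves as the internal oracle; on convex
     sections the two methods agree within 1%, and on non-convex
     (crescent) sections the hull is a strict upper bound.
5. The midsubstance CSA is the unweighted mean over slabs whose center
   lies in the middle 50% (configurable) of the z-extent. The excluded
   outer quarters correspond to the flared bony-insertion regions, whose
   geometry should not contaminate the tissue-level CSA.
6. Optionally, CSA is normalized to bone size as
   `100 * CSA / footprint_area` (percent of tibial plateau).

Report tables round to two decimals, half away from zero; machine-readable
outputs keep full precision.

## Meniscus regional geometry

The meniscus mesh is rotated to an anatomic frame (x = medial–lateral,
y = anterior–posterior, z = proximal–distal) supplied by the user — the
derivation of that frame from scanner axes is a manual step outside this
package. Three regions are then measured:

- **central**: three contiguous coronal slabs (stacked along y) centered
  at the circumferential apex — the point of extreme x toward the tissue
  side (lateral-most for a lateral meniscus, medial-most for a medial
  one).
- **anterior / posterior horn**: three contiguous sagittal slabs (stacked
  along x) centered at the x-position of the horn's y-extremum, where the
  horn is the subset of points beyond the cloud centroid toward anterior
  or posterior. The center is clamped so all three slabs lie on tissue;
  at a free end this shifts the window inward by at most 1.5 slab
  thicknesses. Centering on the extremum point rather than on a mean of
  an extremum neighborhood avoids a bias we observed on phantoms: the
  gently sloping outer rim otherwise drags the window away from the horn
  tip and inflates widths by several percent.

Slab thickness defaults to the source voxel size; the study protocol never
states the physical thickness of a "slice", so tying it to scan resolution
is the natural reading. Within each slab, flattened to its plane, ten
equally spaced stations are taken across the horizontal extent and the
vertical span of points recorded at each (heights); widths mirror this
with vertical stations and horizontal spans. The per-slice value is an
aggregation over stations — **max** by default, **mean** available. The
protocol text says regional values were averaged while the corresponding
figure caption says maxima were recorded; both modes are implemented and
logged, with max as default since a span measurement of a wedge-shaped
cross-section is most naturally its largest extent. The regional value is
the arithmetic mean over the three slices.

Measurement directions are axis-aligned spans in the anatomic frame, not
local-normal spans; at curved horn slices this convention (which the
source protocol leaves unstated) is applied consistently.

## Footprint

The tibial plateau footprint is a single axial segmentation slice at the
plateau's widest point. Its area is the segmented volume divided by the
voxel height, which for isotropic voxels reduces to
`n_voxels * voxel_size^2`; the implementation enforces the single-slice
precondition and reports the offending indices otherwise. MRI-vs-microCT
validation consumes already-measured paired areas and reports a paired
rank-sum test plus Bland–Altman bias and limits of agreement.

## Statistics

All cohort analyses are rank-based, with midranks for ties throughout:

- **Kruskal–Wallis** for one-way comparisons (CSA across ligaments within
  a species), tie-corrected H, chi-square p with k−1 df. For combined
  n ≤ 12 the p-value comes from the exact permutation distribution by
  exhaustive enumeration of rank assignments — the chi-square
  approximation is poor in the far tail at those sizes.
- **Post hoc comparisons**: Tukey HSD applied to the pooled midranks
  (default for the ligament analysis, closest to the study's
  "Tukey's tests" after a nonparametric omnibus — a nonstandard pairing
  we surface as an option rather than silently replace), or pairwise
  two-sided rank-sum tests (used for meniscus post hocs). Either family
  is then Bonferroni-corrected (multiply by family size, cap at 1).
- **Rank-sum**: exact null for combined n ≤ 12 without ties, otherwise
  normal approximation with continuity correction; the paired variant is
  the Wilcoxon signed-rank test.
- **ART two-way factorial tests** (align–rank–ANOVA scheme): for each
  effect, the response is aligned by removing the estimated contributions
  of every other effect, the aligned values are midranked over all
  observations, a two-way factorial ANOVA is fitted to the ranks, and
  only the target effect is read off. The defining property — a factorial
  ANOVA on data aligned for effect X has residual sums of squares ~0
  (relative < 1e-8) for every effect except X — is asserted in tests.
  The factors are treated as fixed effects: the specimen-level pairing
  structure of the original design is not described, so no repeated-
  measures machinery is presumed.
- **ICC(A,1)**: two-way, absolute-agreement, single-measurement
  intraclass correlation from the subjects-by-raters mean squares,
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + k/n (MS_C − MS_E))` with k = 2.
  The agreement form is used (it penalizes a fixed rater offset, unlike
  the consistency form, which is also available). Constant data leave the
  coefficient undefined; the result is flagged rather than raised.
- **Bland–Altman**: bias = mean(a − b), limits bias ± 1.96 SD(d) (sample
  SD), plus the least-squares slope of d on the pairwise means as a
  proportional-bias check.
- **Normality/variance gate**: per-group Shapiro–Wilk and pooled Bartlett
  at alpha 0.05, producing a parametric/nonparametric recommendation that
  is logged but never auto-switches the analysis.

p-values below 1e-3 print as "<0.001" in report tables; full precision is
stored.

## Synthetic phantoms and what they do (not) show

No imaging data ships with the package; every stage is validated on
generated phantoms with analytic ground truth:

- **Ligament tubes**: a cross-section (circle, ellipse, or crescent —
  the lune of two circles, giving a non-convex section with closed-form
  area) swept along a straight axis with a constant, linearly tapering,
  or end-flared radius profile. Surfaces are parametric lattices
  triangulated ring-by-ring with constrained-Delaunay caps, watertight by
  construction. Default vertex density 2000 points/mm² gives >100 points
  per 0.05 mm slab at rodent ligament scale.
- **Menisci**: an elliptical cross-section (width 2a, height 2b) swept
  along a circular arc (default 180°, ring radius 2 mm — rat scale), with
  the end fifths of the arc scaled by `horn_scale` (smoothstep blend over
  5% of the arc). Defaults 2a = 1.0 mm, 2b = 0.8 mm, horn_scale 1.2
  reproduce the horns-wider-than-central pattern at about the magnitude
  seen in rat menisci.
- **Footprint masks**: single-axial-slice ellipse (center-in voxelization
  against the analytic pi·a·b) or a seeded freeform blob.
- **Measurement tables**: paired rater/method readings with subject,
  rater-bias, and error variance components (analytic ICC(A,1) target
  recorded), and tidy cohorts drawn around supplied group means — by
  default the published means and SDs for 10 knees per species.

Every generator is a pure function of (spec, seed) with per-operation
independent RNG streams. Noise applies to measurement tables, not phantom
vertices, unless vertex jitter is explicitly requested.

What passing phantom tests does **not** show: phantoms have no partial-
volume blur, no segmentation error, no anatomical curvature of ligaments
(tubes are straight), no meniscal ossicles, and no inter-animal shape
variation. Recovery accuracies measured here (CSA within 2%, regional
widths within 3–5%) are therefore upper bounds on real-data performance,
not estimates of it.

## Numerical choices and problem sizes

- Vertex deduplication on STL read is exact-match, keeping round-trips
  bit-stable; binary STL stores float32, so round-trip tolerance is 1e-6
  mm at millimetre scale.
- Voxelization is center-in by ray-crossing parity along z-columns, with
  a sub-voxel irrational offset of the ray grid so rays never hit mesh
  edges exactly; a 1 mm cube at 0.1 mm voxels yields exactly 1000 voxels.
- Slab counts use a 1e-9 relative tolerance so an extent that is an exact
  multiple of the increment does not spill a degenerate extra slab.
- The midsubstance window is closed on both ends; boundary slab centers
  are included.
- Degenerate (collinear) slab hulls get area 0; empty meniscus stations
  record 0 with a warning.
- Standard problem sizes: phantom tubes ~8k vertices (≈190 points per
  0.05 mm slab), menisci ~36k points; type-I-error simulation 2000
  replicates of 4 groups x n = 10; ICC recovery n = 200; power checks
  40–200 replicates. These sizes put every simulated check comfortably in
  the stable regime while keeping the default suite fast.

## Known limitations

- Ligament length, orientation angle, and bundle-level analysis are out
  of scope, as are insertion-site geometry, meniscal volume, ossicle
  detection, and circumferential length.
- The anatomic frame for menisci is user input; no automatic anatomical
  axis detection is attempted.
- The ART "mixed" design is treated as fixed-effects; with strong
  specimen-level correlation the reported F statistics would be
  conservative or anticonservative depending on the effect.
- Normalized-CSA arithmetic from published summary tables uses the ratio
  of means; per-specimen normalization before averaging (as done in the
  original cohort) differs in the second decimal for some tissues.
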