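# Methods

This note documents the models, conventions and numerical choices behind
`vesselvol`, in the order the pipeline runs.

## Volumes and geometry

The internal representation is a 3D scalar array in fixed (x, y, z) axis
order with per-axis physical spacing, an origin, and an explicit length
unit ("um" or "mm"). Physical coordinates refer to voxel centers;
`origin + index * spacing` is the exact mapping, and every reader
transposes its format's native order into this convention (DICOM
row/col/slice → y/x/z, TIFF page/row/col → z/y/x, SimpleITK z/y/x).
DICOM rescale slope/intercept is always applied so clinical intensities
are in HU; micro-CT grids pass through in scanner-native arbitrary units.
TIFF stacks carry no calibrated 3D spacing, so reading one without an
explicit `spacing=` is an error — a silent 1.0 default would corrupt
every downstream physical quantity. NIfTI persists the unit tag
(xyzt_units); MetaImage and TIFF do not, so the unit is a read-time
argument for those formats.

## Segmentation

Vessels filled with radiopaque cast or contrast agent are segmented by a
single global threshold, with the comparison deliberately *inclusive*
(`intensity >= t`): at exact boundary values this changes voxel counts,
so the convention is fixed and documented. Foreground connectivity is 26
and background 6 — the standard complementary pair — so thin diagonal
vessels remain connected. The threshold can be fixed (e.g. the 180
arbitrary-unit operating point used for cast micro-CT) or suggested
automatically as a surrogate for manual windowing:

- **Otsu**: exact maximization of between-class variance over all splits
  of the sorted unique intensities (not a binned histogram). This makes
  the suggestion deterministic and exactly invariant under increasing
  affine intensity rescales (the foreground set is unchanged), which the
  binned variant cannot guarantee.
- **Percentile**: upper-quantile threshold with the "higher"
  interpolation rule, so the reported value is an attained intensity.

Bone suppression for CTA uses an upper intensity band followed by a
morphological closing to absorb trabecular gaps; the closed region is
unioned with the raw band because closing alone can *shrink* a region
touching the image border (erosion with an empty border). When a
prospective vessel threshold is supplied, the operation warns if the bone
region would swallow >90% of the vessel mask — the signature of a
misconfigured band. Cleanup removes connected components below a size
floor and can keep only the largest (ties broken toward the lowest
component label).

## Centerline graph

Skeletonization is 3D topology-preserving iterative thinning
(simple-point removal, Lee-style, via scikit-image). The contract is what
matters: the skeleton is a subset of the foreground, preserves the
26-connected component count, creates no cavities, and is unit-width.
Two measured artifacts shape the surrounding code:

- **Open tube ends retract.** Thinning a capped tube pulls each free end
  in by up to ~r/2 + 1 voxel; this is inherent to medial-axis thinning,
  not a defect, and the tests budget for it. Closed structures (rings)
  have no ends and recover their full arc length.
- **Perfect symmetry can erase the skeleton.** An even-diameter tube
  whose axis lies exactly between voxel rows can be thinned away
  entirely. `skeletonize` therefore guarantees component preservation
  explicitly: any foreground component left without a skeleton voxel
  contributes its deepest (maximum-EDT) voxel.

Graph construction classifies skeleton voxels by their number of skeleton
26-neighbors: exactly 2 → chain voxel, anything else → node voxel.
26-adjacent node voxels are merged into a single node at their centroid,
so a bifurcation is one node regardless of how thinning resolved the
junction cluster. Chains are traced deterministically (a chain voxel has
exactly two neighbors); closed loops with no node voxel — a circle of
Willis is a cycle, and cycles are first-class — are anchored at their
lexicographically smallest voxel as a synthetic degree-2 node.

**Chain smoothing.** A polyline through raw voxel centers overestimates
arc length by ~5% (staircase effect; measured 1.054× on a digitized
ring). Chain interiors are therefore smoothed with a window-5 moving
average (endpoints pinned; circular for cycles) before any arc-length
use; the smoothed ring length is within ~0.1% of the true circumference.

**Radii.** The radius at a chain point is the inscribed-sphere radius:
the Euclidean distance transform of the mask, computed with physical
per-axis sampling (anisotropy is handled in the transform, never by
resampling the image), read at the nearest voxel. Under the occupancy-0.5
voxelization convention (threshold at half the tube/background contrast)
this estimator is nearly unbiased: on a digital r = 4-voxel cylinder the
on-axis EDT reads 4.12 voxels. A half-voxel boundary-offset correction is
available (`boundary_offset_voxels`) for workflows whose masks are eroded
to "fully inside" voxels, but it defaults to 0 — adding it under the
occupancy-0.5 convention would push the error to +0.6 voxel, past the
0.5-voxel contract the tests enforce.

**Spur pruning** removes terminal edges that are shorter than both a
user length floor and twice the junction radius (thinning artifacts scale
with local thickness), iterated to fixpoint; junction nodes left with
degree 2 are dissolved by merging their chains. Cycle edges are never
terminal and are never removed; an isolated open vessel (both ends free)
is not a spur and always survives.

## Morphometry

A landmark is a named physical coordinate with a snap radius; it attaches
to the nearest chain point (ties broken by lowest edge id, then point
index) and fails loudly with the nearest distance when nothing is in
range. The "3D ruler" diameter is twice the radius at the snapped point.

A segment is anchored at one landmark and walked toward one direction
landmark per arm, routing by weighted shortest path at bifurcations. A
genuine tie between two routes (two equal-length paths within 1e-6
relative) raises an error demanding a waypoint rather than guessing. The
walk accumulates arc length until the requested arm length and cuts the
final subsegment by interpolation; if the route ends first, the arm is
truncated and flagged, never silently shortened. Because the direction
landmark bounds the walkable route, it should be placed at or beyond the
intended arm end.

Each arm is resampled at a fixed arc-length step (default: the smallest
voxel spacing, i.e. voxel-thick subsegments, well-defined on oblique
chains). Subsegment i has length ℓᵢ (Euclidean between consecutive
resampled points), radius rᵢ (linear interpolation at the midpoint) and
volume vᵢ = π rᵢ² ℓᵢ — an exact identity in the table, which makes three
model properties testable to machine precision: cylinder exactness
(π r² L for constant radius), quadratic radius sensitivity
(volume(k·r) = k²·volume(r)), and additivity under splitting. Volumes are
reported in µl (1 µl = 1 mm³ = 10⁹ µm³), which serves both the µm-scale
murine segments (~0.05 µl) and mm-scale clinical segments. Export writes
VTK legacy polylines with a per-point "diameter" scalar plus a CSV twin
whose per-row subsegment volumes sum exactly to the segment volume.

## Phantoms

The generator emulates contrast-cast vessels: bright tubes (foreground
255 on background 0 by default) along analytic curves (lines, arcs,
polylines) with constant or focally stenosed radius profiles, Gaussian
partial-volume blur (physical σ), and seeded additive Gaussian noise.
Occupancy is computed by k³ supersampling of the tube indicator (default
k = 3, which keeps the partial-volume error below the 0.5-voxel radius
tolerance used in the acceptance tests); open tubes end in flat caps
normal to the tangent so the solid volume equals the quadrature of
π r(s)² ds exactly. Noise is Gaussian rather than Poisson — adequate for
reconstructed-CT residual noise and exactly seedable; a seed is mandatory
whenever noise is requested, and identical spec + seed reproduces the
grid bitwise. Preset axes sit on integer voxel centers (see the thinning
symmetry hazard above).

The focal stenosis profile has a full-reduction plateau of width w with
cosine tapers, so the mid-stenosis diameter ratio is exactly (1 − f) and
the plateau volume ratio exactly (1 − f)². The matched sham/SAH pair
preset uses the murine study conditions: 15 µm isotropic voxels, baseline
radius 82.5 µm (sham MCA diameter scale, 165 µm), a 3.5 mm axis, a 0.5 mm
plateau centered 2.3 mm from the proximal end, severity defaulting to
0.20 (the ~20% proximal-artery narrowing reported a few days after
experimental hemorrhage), blur σ = 0.5 voxel, noise σ = 8 intensity
units. Both members share one noise seed, so severity 0 yields a
bitwise-identical pair. What the phantoms do *not* emulate: beam
hardening and streak artifacts, intensity-dependent noise, curved
realistic circle-of-Willis anatomy, or cast filling defects — passing
recovery tests demonstrates the geometry pipeline, not robustness to
scanner physics.

## Statistics

Group comparison uses the unpaired pooled-variance Student t-test (Welch
available behind a flag); zero pooled variance returns p = 1 for equal
means and is an error otherwise. Spearman correlation uses average ranks
for ties with the t-approximation p-value
(t = ρ·√((n−2)/(1−ρ²)), df = n−2); an exact permutation p is available
for n ≤ 10. Bland–Altman reports bias = mean(a−b) and limits
bias ± 1.96·SD(a−b) with the n−1 sample SD. Ratio statistics exclude
zero-denominator rows with a logged reason; exclusions on paired tables
are first-class and auditable (the bundled murine bookkeeping: 15
specimens × 5 sites − 2 cast-artifact exclusions = 73 retained pairs).

Sample sizes are per group: the smallest integer n such that a two-sided
two-sample pooled t-test at level α has power ≥ the target, with power
evaluated exactly from the noncentral t distribution (df = 2n−2,
noncentrality (δ/σ)·√(n/2)), scanned upward from n = 2. The
treatment-study convention takes δ = effect_fraction·|mean_control −
mean_disease| (default fraction 0.8) and σ = the disease group's SD. On
the bundled summaries this reproduces 45 (left M1 diameter), 33 (right M1
diameter) and 7 (right segment volume) per group. The left segment-volume
endpoint yields 12 from the rounded printed summaries (0.07 ± 0.006 vs.
0.044 ± 0.017 µl) while 13 was published for it; the published figure was
evidently computed from unrounded source data, so 12-from-rounded-inputs
is the reproducible value and is left as documented behavior, not
patched.

## Problem sizes and tolerances

Test phantoms use tubes of radius 4–5.5 voxels and lengths of 60–240
voxels at 15 µm spacing — large enough that radius quantization (±0.5
voxel) stays below 12% of the radius, small enough that the full suite
and the matched-pair analysis run in seconds. Acceptance tolerances:
diameters within 0.5 voxel (median over interior chain points, excluding
the retracted ends), segment volumes within 10% of quadrature truth,
stenosis ratios 0.80 ± 0.05 and 0.64 ± 0.08, ring arc length within 2%,
cylinder identities to 1e-12 relative. Tie-breaks (component labels, snap
order, equal-size components) are all deterministic and documented at the
operation; the only stochastic element anywhere is phantom noise, driven
by a single explicit seed.

## Known limitations

- Inscribed-sphere radii underestimate the cross-sectional radius on
  strongly curved or elliptical vessels; the cylindrical model likewise
  assumes near-circular lumina.
- Thinning retracts open vessel ends by ~r/2, so segments should be
  anchored away from free ends (landmark-anchored segments in practice
  are).
- Bone suppression is an intensity-band surrogate, not registration-based
  subtraction of a pre-contrast scan.
- Automatic anatomical labeling is out of scope: landmarks are
  user-supplied coordinates, as in the manual virtual-dissection
  workflow the package replaces.
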