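# Methods

## The measurement

The quantity of interest is the **axes angle (AA)**: the acute angle, in
degrees, between the long axis of a software-predicted tooth root (from a
digital model) and the long axis of the actual root (from CBCT), after
the two coordinate frames have been rigidly registered.  AA is an
undirected-line angle in [0°, 90°]; it carries no information about the
direction (mesiodistal vs labiolingual) of the error, and none is
reported.

A root "long axis" is always a total-least-squares line: the centroid of
a point set plus the principal direction of its centred coordinates (the
first right singular vector), which minimises the summed squared
orthogonal distances.  Near-isotropic point sets have no meaningful axis;
they trigger a warning and a deterministic sign/tie-break (largest
direction component made positive) so that repeated runs agree.

### Predicted-root axis (digital model route)

Fifty points are placed uniformly over the root surface, the apical 10%
of the root length is excluded (the apex is the least reliable part of a
predicted root), and the TLS line is fitted.  "Uniformly" follows the
operator semantics of the workflow being replicated: points are spread
evenly over the surface.  This matters quantitatively: 50 points drawn
i.i.d. area-uniformly on a ~13 mm × 3 mm root leave the fitted direction
with 4–8° of sampling noise, which would swamp the measurement; evenly
spread points (the default, implemented as ~10 cross-section rings × 5
equal-arc points with seeded level and phase jitter emulating operator
variability) recover a straight root's axis to ≤0.15°.  The i.i.d.
variant remains available (`SlicePlanSpec.surface_placement="random"`)
for studying that variance.

### CBCT-root axis (imaging route)

A preliminary axis (vertex-cloud PCA, oriented cervix→apex by comparing
cross-section areas near the two ends) defines slice stations at 0%, 20%,
40%, 60% and 80% of the cervix-to-apex distance, measured as the chord
along the preliminary axis.  At each station the mesh cross-section
outline is computed, `landmarks_per_outline` (4 by default, 5 allowed)
equidistant landmarks are placed on it, and one TLS line is fitted
through all landmarks (20–25 points).  Stray outline loops are rejected
when their centroid lies more than two equivalent radii off-axis.

Two robustness rules address artefacts of voxelised meshes:

* **Cervical-slice guard.** A segmented root ends in a cut at the cervix.
  When that cut is oblique to the scan grid, its voxelised surface is a
  staircase of terraces spanning up to ~0.8 mm axially, and a slice
  through the terraces yields a partial crescent.  Because root taper
  makes the true cervical outline strictly the largest, the 0% slice
  (inset 1% for mesh-level well-posedness) is stepped apically, 1% at a
  time, until its outline is both larger than the 20% outline and
  concentric with the axis (centroid within 0.3 equivalent radii).
* **Leave-one-out slice rejection.** After fitting, one slice is dropped
  only if its outline centroid is >0.25 mm from the line fitted to the
  remaining slices *and* removing it shrinks the centroid-to-line
  residual RMS at least threefold.  A single contaminated slice meets
  both conditions; genuine root curvature spreads residuals over several
  slices and never does.  Without these rules the per-tooth axis error
  tail on 0.3 mm-voxelised roots reached ~16°; with them the error is
  ~0.5° RMS, and undegraded curved roots are unaffected (≤0.06°).

### Registration

Frames are aligned per arch (maxilla and mandible independently) in two
stages, mirroring a manual-then-automatic workflow: (1) Kabsch
closed-form alignment of noisy anatomical landmarks (cervix centre and
apex per tooth, σ = 0.3 mm emulating click imprecision); (2) trimmed
point-to-point ICP on the concatenated crown surfaces — 5 000 area-uniform
source samples drawn once (seeded), exact closest points on the target
surface (k-d tree over triangle centroids + exact point-to-triangle
projection), the closest 90% of pairs feeding a Kabsch update recomputed
from the original samples.  Point-to-point ICP converges linearly under
tangential sliding, so the classical acceleration is included: when
successive parameter updates (quaternion + translation) are nearly
collinear with a stable contraction ratio, the iteration jumps to the
geometric-series limit, accepting the jump only if it does not increase
the RMS.  This cuts iteration counts by roughly an order of magnitude
while preserving the monotone-RMS property.  Crowns only are used:
correspondences against predicted (virtual) roots would bias the
alignment toward the very error being measured.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a clinical dataset (plaster-scan digital
models plus CBCT) that is not publicly available.  Its defaults mirror
the study conditions being replicated: 31 subjects, 12 permanent anterior
teeth (FDI 11–13, 21–23, 31–33, 41–43), 0.3 mm voxel spacing, subject
metadata with 10/31 males, ages 12–40 (mean 19.2, SD 8.1), and Angle
classes I/II/III in proportions 0.5/0.3/0.2 (a typical clinic mix; the
replicated study does not report its class distribution).

* **Teeth** are tapered elliptical tubes (radius ∝ (1−t)^taper, closed
  caps, watertight) with a progressive bend of `apical_curve_deg` over
  the apical third; canines get longer roots and stronger curvature.
  Crowns are blade-like — the labiolingual width collapses toward an
  incisal edge while the mesiodistal width barely tapers — because a
  crown that is a surface of revolution would make rotation about its own
  axis unobservable to ICP, for the generator and for a real scanner
  alike.  Low-amplitude seeded lobes individualise every tooth.  The
  ground-truth axis is the TLS line through the ring centres of the
  cervical 80% of the root, the same anatomical region both estimators
  target.
* **Injected errors** rotate the root about an axis through the cervix
  centre perpendicular to the true axis at a random azimuth, by an angle
  drawn half-normal with per-class scales (centrals 12°, laterals 15°,
  canines 20°, giving medians ≈8.1/10.1/13.5°; chosen once to mirror the
  observed ordering that canines are hardest, and clamped at 45°).
  Half-normal is the natural model for a nonnegative angle.  Optional
  Gaussian vertex jitter (σ = 0.05 mm) roughens the predicted root.
* **CBCT-style degradation** is voxelise → Gaussian point-spread blur
  (σ = 0.7 voxel) → marching cubes at 0.5.  The blur models partial-volume
  graduation: raw binary occupancy through marching cubes carries a ~8%
  staircase area bias, while with the PSF the extracted sphere area is
  accurate to <1%.  No beam hardening, noise, metal artefacts or
  soft-tissue/bone context are modelled, and roots are assumed
  pre-segmented per tooth.
* **Frames**: each arch's CBCT-side meshes are moved by a random rigid
  transform (rotation ≤10°, translation ≤5 mm by default), retained as
  ground truth for evaluating registration.

Passing recovery tests on this generator therefore shows that the
*measurement chain* (sampling, slicing, fitting, registration, angle) is
unbiased and precise under realistic resolution loss — it does not
validate the anatomical realism of any root-prediction algorithm, nor
does it reproduce the per-tooth AA magnitudes of any particular clinical
cohort, whose distributions are a generator input, not an output.

## Statistics

Per-tooth descriptives use linear interpolation between order statistics
for quartiles (stated here because conventions differ).  Group
comparisons are nonparametric, as AA is nonnegative and typically skewed:
Mann–Whitney U between sexes per tooth (exact enumeration p when the
combined sample is ≤12 and tie-free, otherwise tie-corrected normal
approximation with continuity correction) and Kruskal–Wallis between
Angle classes, each family Bonferroni-adjusted across the 12 teeth.  An
age comparison uses a Mann–Whitney on a median split of age; the split
value is recorded in the report since no standard grouping exists.
Repeatability between two measurement rounds is summarised per tooth by
Bland–Altman bias and 95% limits of agreement (classical 1.96 × SD of
differences, n−1 denominator) plus a paired t-test for systematic error;
teeth whose LoA half-width exceeds 4.5° are flagged.

The Dupont–Plummer paired-design sample size solves
n ≥ (s/d)² (t_{α/2,n−1} + t_{β,n−1})², which is implicit in n through
the t quantiles.  Since t quantiles exceed normal quantiles, the normal
approximation gives a lower bound; the solver scans upward from it to the
first satisfying integer (the satisfying set is upward-closed), with a
floor of n = 2.  At s = 5°, d = 3°, α = 0.05, power 0.80 this gives 24.

## Numerical choices and conventions

* Coordinates are millimetres, right-handed; STL vertex welding at
  1e-6 mm; binary STL stores float32, so round trips agree to ~1e-5 mm.
* Cross-sectioning nudges vertices lying exactly on the slice plane by
  +1e-9 mm along the normal; open section chains are closed when the
  endpoint gap is <0.5 mm and discarded otherwise.
* Outline landmark walks start at the minimum-x vertex (ties by y, z);
  the fitted axis is near-invariant to this phase choice.
* ICP defaults: 50 iterations, RMS-change tolerance 1e-6 mm, trim 0.9,
  5 000 source samples.  From a landmark initialisation it converges in
  10–20 iterations; identity-initialised recovery of ≤10° offsets
  benefits from raising `max_iterations` to a few hundred.
* All randomness flows through `numpy` Generators seeded from explicit
  integers; cohorts are bit-reproducible from `(spec, seed)`.
* Problem sizes in the test suite: the end-to-end recovery check runs the
  full 31-subject × 12-teeth cohort at 0.3 mm; unit tests use 2–8 subject
  cohorts and 4-tooth arches, which already exercise every code path.

## Known limitations

* Single-rooted anterior teeth only; no multi-rooted morphology.
* The CBCT emulation is geometric (resolution + PSF); intensity physics
  is out of scope, so threshold-segmentation errors of real scans are not
  represented.
* Registration assumes both frames at 1:1 scale (true of plaster scans
  and CBCT); no scale or non-rigid estimation.
* The AA is a magnitude; decomposition into clinical directions is
  deliberately not provided.
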