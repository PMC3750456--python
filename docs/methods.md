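# Methods

## Coordinate frame and voxel model

All physical coordinates are millimetres in one fixed patient-space
convention: +x toward the patient's right, +y anterior, +z superior.
NIfTI volumes are reoriented to the closest canonical orientation on read
and oblique acquisitions are rejected; NRRD files must be axis-aligned.
A voxel is a cell of size `spacing` centred at `origin + index·spacing`,
and a mask refers to cell centers, so cavity volume is exactly
`count × s_x s_y s_z`. Axial slice spacing above 1 mm triggers a warning:
sub-millimetre sampling is assumed throughout, and volumetric accuracy
degrades roughly linearly with slice thickness. No particular frame was
mandated by the workflow this package operationalizes; the choice here is
internal and only needs to be used consistently.

## Segmentation and volumetry

The bony orbit is an open cavity; manual per-slice marking has no
algorithmic definition, so segmentation is recast as a reproducible 3-D
procedure: threshold bone (`bone_threshold`, default 300 HU-like for CT —
between soft tissue and cortical bone; CBCT intensities are uncalibrated,
so the threshold is a per-modality configuration value), morphologically
close the bone mask with a ball of `closing_radius_mm` (default 1 mm) to
seal fracture gaps, and flood-fill (6-connectivity) the non-bone space
from a seed placed 15 mm behind the rim-point midpoint. A fill exceeding
`max_volume_ml` (default 60 ml, more than twice any plausible orbit) is
reported as a leak with the advice to raise the closing radius: this is
the algorithmic stand-in for the visual leak control a human operator
performs. The closing radius must exceed roughly half the fracture gap at
fine voxels and the full gap at 1 mm voxels.

The anterior border is the plane containing the straight line through the
lateral (L) and medial (M) orbital rim points and the axial slice
direction — the natural 3-D reading of a per-slice rim line. Voxels whose
centers lie anterior to that plane (signed distance ≥ 0, normal oriented
anteriorly) are removed; volumes are reported only for clipped masks. The
per-slice profile (area and subvolume per axial slice) partitions the
total volume exactly.

## Mirror template and registration

The midsagittal plane is the total-least-squares (SVD) plane through ≥ 3
non-collinear midline landmarks, normal oriented left-to-right. The
unaffected cavity surface is extracted by marching cubes at iso-level 0.5;
an optional Gaussian pre-smoothing of the binary indicator (sigma in
voxels; 0 in the bare function, 1.0 in the pipeline) removes the
half-voxel staircase and gives ~0.05 mm surface accuracy on smooth
anatomy, at the cost of rounding features below ~2 voxels. Extraction
preserves enclosed volume to well under the 3% contract against the voxel
count. Faces are oriented outward (positive divergence-theorem volume);
reflection across the mirror plane flips the winding to keep them outward.

Alignment to the reconstructed side is rigid only — the template is the
patient's own mirrored anatomy, so scale or deformation would destroy the
comparison — using trimmed point-to-plane ICP: correspondences are exact
nearest points on the target surface, pairs farther than
`max_correspondence_mm` (5 mm) are rejected, the worst `trim_fraction`
(10%) of the remainder is dropped, and the linearized 6-DOF step is solved
by least squares with a Rodrigues update. Defaults: 100 iterations,
convergence when the mean correspondence distance changes by less than
1e-4 mm, at most 4000 ROI vertices (uniform stride). There is no random
sampling anywhere, so identical inputs give bit-identical transforms. A
closed-form Kabsch landmark pre-alignment is available for initialization;
in the phantom pipeline the mirrored template already lies in the target
frame and the identity suffices.

The matching ROI excludes the reconstructed wall, the rim band, and
unlabeled vertices, keeping the roof and intact walls. This is the load-
bearing design point: registering *with* the deformed wall included biases
the alignment toward absorbing the deformation, and the regression tests
measure exactly that (with the floor excluded, the recovered floor
deviation stays within 10% of the injected amplitude).

## Deviation mapping

For each template vertex the minimal perpendicular distance to the target
surface is computed exactly: candidate closest features include face
interiors, edges and vertices (Ericson's region classification,
vectorized). A KD-tree over triangle centroids prunes candidates; a query
is provably complete once every triangle whose centroid lies within
`best distance + max triangle circumradius` has been examined, and an
exhaustive all-triangles scan serves as the independent oracle in tests
(agreement to 1e-9 mm). Exact ties go to the smallest triangle index.
The sign comes from the angle-weighted pseudonormal at the foot point
(face normal / edge-average / angle-weighted vertex normal), which is the
standard robust inside/outside test for watertight meshes: positive
deviation means the reconstructed surface lies outside the template cavity
(toward bone, an enlarged orbit). Vertices with no correspondence within
5 mm are flagged missing, excluded from moments, and reported as a
missing fraction — never silently zeroed. Display colors interpolate
linearly green→red over [0, +1.5 mm] and green→blue over [0, −1.5 mm],
saturating beyond; 1.5 mm is the configurable clamp chosen as the scale of
clinically reported worst-case deviations. Degenerate (zero-area) faces
are dropped before querying.

## Region partition

Anatomical wall names carry no geometric rule, so walls are defined by
angular sector around the orbital axis (rim-point midpoint → apex; the
apex landmark, or the deepest vertex from the rim plane): floor = inferior
sector, medial = sector toward the midsagittal plane, lateral = opposite,
roof = superior, with 45° half-angles by default. Depth is normalized
along the axis (0 at the rim plane, 1 at the apex) and each wall splits
into anterior [0, ⅓), central [⅓, ⅔) and posterior [⅔, ∞) thirds —
boundaries closed on the deeper side, so a vertex exactly at ⅓ is central.
Vertices anterior to, or within 1 mm behind, the rim plane are labelled
`rim`: anterior clipping leaves a flat face on the mesh exactly at the rim
plane, and that face is rim surface, not wall. The labels partition the
vertex set; region areas use barycentric (one-third) vertex areas and sum
to the total area.

The medial-wall/floor transition zone — the clinically critical junction —
is reported as an extra, overlapping band: vertices on the medial or floor
sector within 2 mm arc distance of the −45° boundary.

Implant segmentation thresholds the post-operative volume above bone
intensity (phantom calibration: bone 1200, implant 3000 before the CBCT
intensity scale) with 26-connected components, because a voxel-thin metal
sheet draped over a curved wall steps diagonally; components under
`min_voxels` (10) are dropped, and the size of the largest component flags
thresholds low enough to leak into bone. Coverage is the area fraction of
each region whose vertices lie within `projection_distance_mm` (2 mm,
since the mesh rests on or just under the wall surface) of an implant
voxel; when the labelled mesh is a template that deviates from the
reconstructed anatomy, coverage is measured at the per-vertex foot points
on the reconstructed surface, where the implant actually sits.

## Cohort statistics

Within-patient volume comparisons use a paired two-sided t-test by default
(volumes are plausibly normal) with the Wilcoxon signed-rank test as an
option; identical vectors (zero-variance differences) report p = 1 with a
degeneracy flag instead of NaN. Modality agreement adds Bland–Altman mean
difference and 1.96·SD limits. No multiple-testing correction is applied
by default — matching single-comparison reporting practice — with Holm
adjustment available. Group summaries (mean ± SD by gender, fracture
class, treatment group) flag single-record strata and keep empty strata as
n = 0 rows.

## Synthetic phantoms

Each orbit is an ellipsoid cavity (semi-axes a = 16 mm lateral, b = 17 mm
vertical, depth c solved so the rim-clipped half-ellipsoid volume
(2/3)πabc equals the calibration target, 26.6 ml — the reported adult male
mean; c ≈ 46.7 mm, a realistic orbital depth) inside a 2.5 mm bone shell
in a soft-tissue block, mirrored about x = 0 on a grid whose x-centers are
exactly symmetric. The anterior half of the ellipsoid is removed by the
rim plane through L and M; a bone lid 3 mm anterior of the rim closes the
cavity so the flood fill is bounded (real orbits are open anteriorly — the
rim plane is the volumetric boundary either way, and the lid region is
clipped off before any volume is reported).

Fractures displace the floor (or medial wall) outward by a flat-top bulge
(constant core, cosine-squared taper); the footprint scale is solved by
bisection on exact voxel column counts so the added cavity volume hits the
requested target to within one voxel layer, and an unattainable target
(given the amplitude) raises an error stating the attainable maximum. The
default — 3.4 ml added at 8 mm amplitude over most of the floor — emulates
a complete floor fracture with posterior-ledge involvement, the pattern
with the largest reported enlargements; herniation depth of this order is
at the severe end of the clinical range and follows from requiring 3.4 ml
through a floor-sized footprint. A fracture gap of `defect_gap_mm` (1 mm)
is cut around the displaced fragment so an unclosed bone mask genuinely
leaks. The displaced fragment is also rasterized at the 3×3
neighborhood-maximum displacement, because a steep displacement gradient
would otherwise shear the voxelized shell open between adjacent columns at
coarse spacings.

The reconstructed state restores the wall with a small residual bulge
(default 1.5 mm on the anterior floor — the scale and a reported location
of worst-case deviations) and an implant sheet: the 1 mm layer just
outside the reconstructed cavity surface, restricted to the floor's 45°
sector and a near-rectangular (p = 4 superellipse) footprint covering the
full floor or its anterior two-thirds.

Imaging is emulated as intensity plateaus (soft tissue 50, bone 1200,
implant 3000) scaled per modality (CT ×1.0, noise σ = 20; CBCT ×0.6,
σ = 40 — lower dose, uncalibrated intensities) plus additive Gaussian
noise from a single seeded generator; identical specs give bit-identical
volumes. Ground truth records exact volumes (analytic and voxel-counted),
landmarks, planes, seeds, footprints, implant voxels and an exact labeling
function for any surface point.

What the phantom does **not** emulate — and hence what passing tests do
not show about clinical data: real orbital shape (nasolacrimal fossa,
anterior-floor concavity), partial-volume intensity blur, CT physics
(beam hardening, metal artifacts around titanium), soft-tissue structures
inside the orbit, patient-level facial asymmetry beyond a global scale
factor, and landmark-picking error beyond additive noise. Clinical
agreement percentages and deviation accuracies will be lower than the
phantom figures; the phantom establishes algorithmic correctness, not
clinical performance.

The simulated cohort draws demographics from the reported proportions
(58:36 male:female; fracture classes 34/20/32/4 with the complex group
split 32 medial / 4 lateral; navigation for complex and posterior-ledge
patterns, 60:34 overall) and volumes from the gender-specific normals
(26.6 ± 2.8 / 25.2 ± 2.6 ml). CBCT re-measurement noise is zero-mean
(SD 0.8 ml) by default: the source report shows slightly different CT and
CBCT group means yet states the paired difference was not significant, and
at these sample sizes both cannot hold, so the generator follows the
significance statement; a `modality_bias_ml` parameter exposes the
alternative.

## Pipeline

`run_case` chains segmentation (four orbit/modality combinations), mirror
template, labeling, ROI registration, deviation mapping and implant
coverage, logging one line per stage. Outputs are deterministic given the
configuration and carry a SHA-256 config hash (the output directory is
excluded from the hash — relocating a run does not change its science).
Completed stages persist their artifacts under `stages/` keyed by that
hash, so an interrupted run resumes from the last completed stage and a
config change invalidates the cache. Stage failures abort with the stage
name and a remediation hint.

## Problem sizes and runtimes

The validation suite runs phantoms at 0.5 mm voxels (≈ 3.3 M voxels,
≈ 25 k surface vertices per orbit) for volumetry, registration and
deviation checks, and 0.8–1.0 mm for auxiliary checks; the full suite
takes about half a minute on one CPU, and `scripts/acceptance.py` a few
seconds. Statistical calibration uses 1000 null and 500 shifted
replicates at n = 30 pairs. These sizes were chosen as the smallest at
which voxelization error is comfortably inside every tolerance
(discretization error at 0.5 mm is ≈ 0.6% of volume against the 2%
contract).

## Known limitations

- Wall/third boundaries are geometric conventions (45° sectors, equal
  depth thirds); other conventions would shift region statistics without
  changing the deviation field itself.
- The anterior clip plane depends on two manually picked rim points; its
  orientation error propagates directly into the volume (≈ 0.4 ml per
  degree at these cavity sizes).
- Point-to-plane ICP assumes a reasonable initial pose (here, mirror
  symmetry or landmark pre-alignment); it will not recover from
  gross (> ~15°) mis-poses.
- CBCT intensity is modelled as a global scale; real CBCT non-uniformity
  may require locally adaptive thresholds that are out of scope.
- The volumetric flood fill requires a closed bone boundary; severely
  comminuted defects may need closing radii large enough to round off
  genuine anatomy, which the leak guard reports but cannot repair.
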