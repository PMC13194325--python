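# Methods

## The model

The core object is a linear point distribution model (PDM). A cohort of S
surfaces is re-expressed as ordered point sets of N points with index-wise
anatomical correspondence; the model is the mean shape M̄ (the reference
geometry), the orthonormal eigenmodes φᵢ of the sample covariance of the
S×3N data matrix and their eigenvalues λᵢ (mm², the variance along each
mode). Shapes are synthesized as

    x(w) = M̄ + Σᵢ wᵢ √λᵢ φᵢ

with weights in standard-deviation units; the study convention explores
±3 SD along one mode at a time. The decomposition uses the thin SVD of the
centered data matrix (stable for 3N ≫ S) with sample (S−1) normalization —
the variance percentages reported are therefore unbiased sample fractions.
Eigenvector signs are fixed by making each mode's largest-magnitude
training coefficient positive, so fits are bit-reproducible.

Four models are built per cohort, mirroring the surgical workflow: (1) the
native proximal femur, (2) the femur after neck osteotomy (plane cut,
capped), (3) the intramedullary canal (occupancy Boolean subtraction of
the bone shell from the filled osteotomized femur), (4) the reconstructed
femur (osteotomized femur grouped with the seated stem into one closed
surface).

## Synthetic anatomy

The generator composes a signed-distance field: a shaft of revolution, a
neck capsule, a head sphere, greater/lesser trochanter bumps (polynomial
smooth-union, 3 mm blend at neck junctions, 5 mm at trochanters), minus an
intramedullary tube that funnels from the diaphysis into the neck
direction. The zero isosurface is sampled on a grid of pitch
`mesh_resolution` (default 1 mm) by marching cubes, guaranteeing closed
manifold output for any admissible parameters. Everything is built
directly in the anatomical frame of a left femur (x medial, y anterior, z
proximal); virtual posterior-condyle landmarks are emitted analytically
because the meshes are proximal-only. A right femur is the same geometry
with y negated — which is exactly how a right femur appears when expressed
in its own condyle-based frame.

Key default parameters (units mm/deg): shaft radius 15, cortical thickness
7, neck radius 13, neck length 50, head radius 23, NSA 125, version 15,
valgus 7, shaft length 175 (standardized later to 150). The neck direction
is constructed so that the angle to the shaft axis equals the requested
NSA exactly while the axial-plane azimuth equals the requested version
exactly; both are therefore exact ground truth. The osteotomy plane
defaults to a cut perpendicular to the neck axis 8 mm above its base. The
stem is a tapered body filling 85% of the local canal radius with a
prosthetic neck at a fixed design NSA of 132° and a prescribed stem
version.

Two geometric consequences of this construction are worth knowing. First,
with a tilted (valgus) shaft, rotating the neck azimuth at fixed NSA
necessarily changes the head's height and offset slightly — femoral
torsion around a tilted axis is not a symmetry of the vertical direction.
Single-factor "version only" experiments therefore use a vertical shaft,
where torsion is an exact symmetry of the remaining anatomy. Second,
ground-truth volume is not closed-form for the blended union; it is
integrated by occupancy counting of the analytic field at 0.7 mm pitch
(≈0.1–0.5% accurate), independently of the emitted mesh.

Surface noise, when requested, is seeded per-vertex displacement along
normals, low-pass filtered by two neighbour-averaging passes.

### What the generator does and does not emulate

It emulates the *geometric* content of segmented CT anatomy: smooth
cortical surfaces with realistic feature scales, a hollow canal, planned
osteotomy cuts, a press-fit stem construct, and population variation in
the parameters of interest. It does not emulate segmentation artefacts
beyond isotropic surface roughness, cortical density, osteophytes or
pathological shape variants, and its necks/heads are idealized capsules
and spheres. Passing tests therefore demonstrate that the pipeline's
measurements and eigen-analysis are correct on known anatomy of realistic
scale — not that its correspondence engine would be adequate for every
pathological clinical shape.

## Alignment and correspondence

The surgical frame is built from landmarks: origin at the posterior
condyle midpoint, x̂ the condylar axis lateral→medial, ẑ toward the
intertrochanteric crest orthogonalized against x̂, ŷ = ẑ × x̂. Because x̂
is lateral→medial on both sides, anteversion stays positive after right
femora are mirrored (reflection across the frame's x–z plane). Shapes are
standardized to 150 mm proximal extent by a capped transverse cut and then
aligned by translation only, anchoring the distal cut-face centroid —
insensitive to head/trochanter size, and rotation/scaling are deliberately
never applied.

Correspondence is template-to-target: the cohort member nearest the
cohort's bounding-box center is isotropically remeshed (voxel + isosurface
+ Taubin smoothing, calibrated to the requested point budget ±10%) and
each template vertex is projected onto the target along its outward
normal (bidirectional Möller–Trumbore with KD-tree candidate pruning,
nearest-point fallback), with the displacement field Laplacian-smoothed on
the template graph between iterations and a pure projection last, so every
corresponded point ends on the target surface.

Plain normal shooting gives *spatial* correspondence, which under femoral
torsion lets head points lag behind the rotating anatomy and smears the
mean shape. The engine therefore accepts matched landmark arrays (head
center, GT tip, LT apex, crest, condyles, plus fixed distal-shaft anchors)
and first carries the template by a Gaussian radial-basis displacement
warp through those landmarks. The Gaussian kernel (40 mm bandwidth, the
spatial scale of proximal-femoral features) has zero gradient at each
control point, so each landmark's neighbourhood rides rigidly with it and
the warp decays to identity far from all controls — unlike the classic
r-kernel thin-plate spline, whose long-range affine shear was measurable
as a spurious correlation between version and corresponded
lesser-trochanter position.

## Measuring shapes

* Shaft axis: line fit through transverse-slab centroids of the distal
  45% of the z-extent, with one outlier-rejection pass (drops slabs
  contaminated by the cut face or trochanter flare).
* Head: iteratively reweighted sphere fit seeded at the head landmark,
  with a trimming pass that rejects the neck-junction bulge, and an
  anatomical plausibility band (12–40 mm radius) so canal domes or
  arbitrary blobs are not mistaken for heads.
* Neck axis: sections perpendicular to the current neck-direction
  estimate; the free neck tube is identified as the sections whose girth
  is within 2% of the minimum (the waist), and the axis runs from their
  centroid mean to the head center (sub-half-degree accurate at 1.2 mm
  pitch).
* Version: axial-plane azimuth of the neck axis against x̂, anteversion
  positive, folded into (−90°, 90°]. NSA: 3D angle between neck and shaft
  axes with the conventional obtuse opening. Varus/valgus: coronal lean of
  the shaft axis. VFO/HFO: head-center height above the LT apex and
  perpendicular distance from the shaft axis.
* Head-less models (post-osteotomy femur, canal): axial rotation is
  measured on the planar osteotomy face. The default surrogate is the
  azimuth of the cut-face normal, which equals the version exactly for a
  neck-perpendicular cut. The medial–lateral extreme-point chord is also
  implemented (`method="chord"`), but on a near-circular perpendicular
  cut face the extreme-x chord of the section is degenerate and does not
  track the neck azimuth (its closed-form azimuth is roughly −2× the
  version at NSA 125°); it is meaningful only for elongated oblique
  faces, hence not the default.

### Measurements on synthesized shapes

±3 SD shapes exist only as corresponded point sets, so their measurements
use the correspondence itself rather than geometric re-detection: the head
sphere is fitted to a fixed template vertex set (the spherical cap within
1.08× the measured head radius of the head center), the LT reference is
the tracked LT patch centroid, the cut face is the tracked planar-face
vertex set, and the shaft axis runs through per-slab *circle-fit* centers
of index groups frozen on the mean shape (circle centers are insensitive
to the azimuthally nonuniform vertex density corresponded points can
develop; the frozen slabs cover the distal 30%, clear of the LT bump).
Freezing the selections removes selection jitter between the −3 SD and
+3 SD shapes, which would otherwise dominate the feature change scores.

## PC labelling

For each of the first k (default 3) PCs, shapes at −3 SD, mean and +3 SD
are synthesized and measured. Each feature's change score is
|f(+3SD) − f(−3SD)| divided by a normalizer, default the cohort SD of that
feature (features are incommensurable across deg/cm/cm³), floored at the
measurement's repeatability scale (1° for versions and NSA, 0.5° for
varus/valgus, 0.05 cm head radius, 0.1 cm offsets, and 2.5% of the cohort
mean for volume, whose repeatability through the correspondence layer is
relative). The top-scoring feature labels the PC; features scoring at
least 0.75× the maximum are reported as a combination, with deterministic
tie-breaking.

## Cohort experiments

Factor-isolation experiments draw factor values *quantile-balanced*: the n
normal quantiles at (i+0.5)/n in seeded random order, so the sample
mean/SD match the nominal values almost exactly even at n = 31, and the
±3 SD synthesis is symmetric. Two-factor designs pair the second factor by
the seeded permutation minimizing |correlation| among 64 candidates, and
the second factor's SD is calibrated from measured shape sensitivities
(central differences through the correspondence layer) so the induced
shape variances hit the requested ratio by construction. The NFV-vs-PFV
contrast draws NFV ~ N(19°, 9°) and, for independent seating,
PFV ~ N(15°, 10°) — the distributions the cohort literature reports — and
compares a paired t-test against a seeded 10,000-draw sign-flip
permutation test (the t-test's distribution-free cross-check).

## Numerical choices

* Voxelization is z-scanline parity counting with the lattice origin
  offset by an irrational sub-voxel amount, so rays through voxel centers
  cannot hit mesh edges/vertices exactly; occupancy isosurfacing filters
  the binary field with a Gaussian (σ = 0.9 voxel) before marching cubes,
  keeping the surface at the half-occupancy level (canal volumes accurate
  to ~2% at 0.5 mm pitch).
* Cut capping triangulates the section polygon as a fan around its
  centroid when the polygon is star-shaped, with an ear-clipping fallback;
  cap boundary vertices are snapped onto the plane to 1e-6 mm.
* STL reads weld duplicate vertices at 1e-6 mm (below anatomical signal,
  above float32 noise); PLY is written with double-precision coordinates
  so round-trips are exact.
* Sphere fitting is the algebraic least-squares solve followed by one
  Gauss–Newton refinement pass.
* Degenerate inputs raise: open meshes name their boundary-edge count,
  inverted orientations are not silently absolute-valued, a head on the
  shaft axis reports an undefined neck direction, identical training
  shapes are a degenerate cohort.

## Problem sizes

The default test and acceptance runs use cohorts of 31 (the per-sex cohort
size of interest), 50 recovery femora at 1.2 mm pitch, n = 62 for the
version contrast at 2.2 mm pitch, and 800–1200-point templates; these
sizes keep full runs in the minutes range while leaving every tolerance
comfortably met. All stages are deterministic under the study seed.

## Known limitations

Correspondence is geometric-plus-landmarks, not groupwise-optimized
(minimum description length); exact mesh Booleans are out of scope (the
Boolean step is voxel-based); the linear PDM represents rotational
variation by chords, so ±3 SD shapes of a strongly rotating mode inflate
radii by second-order terms (visible as a few mm of head offset at ±27°);
and the stem model is a geometric stand-in for a triple-taper implant, not
a manufacturer geometry.
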