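# Methods

## Problem and model

Serial 3D facial surface scans (CBCT-derived or stereophotogrammetric, in
millimetres) of a growing individual differ for three confounded reasons:
arbitrary acquisition pose, true morphological change, and acquisition
noise. To measure the change, the later scan (T1) must first be rigidly
relocated onto the earlier one (T0) using only a reference area assumed
morphologically stable; residual surface-to-surface distances elsewhere
then quantify growth. The choice of reference area is the scientific
crux: any growth *inside* the reference area is absorbed by the best-fit
and redistributed as spurious change everywhere else.

`facesup` implements this workflow end to end and validates it against a
synthetic gold standard with known ground truth.

### Registration

Superimposition is rigid point-to-plane ICP restricted to the masked
reference-area vertices of the moving T1 surface:

E(R, t) = Σᵢ [ nᵢ · (R sᵢ + t − cᵢ) ]²

with cᵢ the *exact* closest point (vertex, edge or face interior) on the
fixed T0 triangulated surface and nᵢ the supporting-surface normal there
(face normal, averaged across the two faces on an edge, area-weighted at a
vertex). Each iteration solves the small-angle linearisation in closed
form (6×6 normal equations via SVD) and projects the update onto SO(3),
so the pose is exactly rigid at all times; no scale is ever estimated.
Closest-point search uses a KD-tree over target vertices for pruning that
preserves exactness: the nearest-vertex distance d bounds the surface
distance, so all triangles with a vertex within d plus the longest edge
length are tested in closed form.

Protocol settings (defaults): 100% overlap, 100% point sampling (every
masked vertex participates, no trimming), exact nearest neighbours,
overhang exclusion (correspondences whose closest point lies on a border
edge or border vertex of the open target are discarded), at most 50 inner
iterations with an early stop when the mean absolute point-to-plane
residual improves by < 1e-6 mm; a step that would increase the residual
is rolled back. The converged inner loop is then re-run from the current
pose (typically 2–5 times) until the mean absolute point-to-point
correspondence distance improves by < 1e-4 mm, capped at 10 runs. The
outer stop metric is point-to-point mean absolute distance; the
point-to-plane residual is recorded alongside per run.

If the masked geometry leaves the 6×6 system rank-deficient (for example
all correspondences on one plane, which permits in-plane sliding), the
minimum-norm solution is taken — unconstrained components come out
exactly zero — and a `DegenerateGeometryWarning` is emitted.

Before ICP the pipeline pre-aligns T1 with a least-squares rigid
(Kabsch) fit of the shared landmarks, which places any realistic
acquisition misalignment inside the ICP convergence basin.

### Regions

All region definitions live in a face-aligned frame derived from the
landmarks: origin at soft nasion, +x toward the subject's right
exocanthion, +y from soft pogonion toward glabella, +z anterior
(Gram–Schmidt in the order x, y). Five candidate reference areas are
parametric combinations of boxes, ellipsoids, spheres and half-spaces
(all constants in `regions.AreaConfig`): the whole face minus eye, mouth
and nose-tip exclusions (area1); forehead/glabella plus nasal base
(area2); the upper half of the face minus eyes and nose tip (area3); a
small forehead rectangle plus the mid-nose strip and two infraorbital
patches of radius 12 mm about each orbitale (area4); and area4 without
its forehead rectangle (area5). The seven measurement patches are the
100 vertices nearest (Euclidean) to their seed landmark — soft nasion,
soft A point, soft pogonion, both zygia, both gonia — with distances
rounded at 1e-9 mm and ties broken toward the lower vertex index, making
the selection deterministic and invariant under rigid motions. Patches
are selected once on T0 and duplicated onto other models by
nearest-vertex transfer.

### Distance analysis

Signed distance maps are evaluated at the reference mesh's vertices as
exact point-to-surface distances, signed by the dot product of
(closest point − vertex) with the reference vertex normal: a comparison
surface lying along the outward normal — anterior movement of a growing
face measured from T0 — reads positive. MAD for a patch is the mean of
the absolute signed distances over its vertices. Note that MAD measures
closest-surface distance, not displacement: a rigid offset of d oblique
to the patch normals reads slightly below d (by the patch-average
|cos θ|); on the synthetic chin this factor is ≈0.92, so a 2 mm imposed
protrusion reads ≈1.84 mm even under a perfect registration.

Method-vs-gold comparisons place the *same* T1 model under two
transforms; the gold placement is the reference, per-patch MADs between
the placements summarise the discrepancy, and their per-patch sums over
subjects form the difference table. Reference-area congruence is the MAD
between the superimposed T1's masked reference vertices and the T0
surface. Reproducibility is the signed per-patch difference between two
full passes whose landmark selections differ by an independent uniform
±1 mm perturbation (re-deriving masks and re-running ICP).

### Statistics

Distance measurements are bounded below by zero and right-skewed, so the
comparison battery is nonparametric: Shapiro–Wilk plus
Kolmogorov–Smirnov normality screening (the KS test uses the Lilliefors
correction for estimated mean/sd, the common statistical-software
default), Kruskal–Wallis on mid-ranks with tie correction and the χ²
approximation (adequate at the 7–18 observations per group in scope),
and Dunn's pairwise z-tests on pooled mid-ranks with Bonferroni
multiplication by the number of pairs, clamped at 1. All tests are
two-sided at α = 0.05. An all-identical sample is reported as H = 0,
p = 1; a constant sample is non-normal by convention.

## Synthetic ground truth

No serial facial scans are redistributable, so validation runs on a
parametric generator. The face is a height field over a trimmed
half-ellipsoid dome with closed-form features: nasal bridge and tip, brow
ridge, glabellar prominence, orbital sockets ringed by an orbital-margin
ridge, cheeks, lips and chin. The orbital rim and glabellar terms are not
cosmetic: they supply the lateral surface gradients that make the
forehead + mid-nose + infraorbital reference area (area4) identifiable —
without them the fit can slide laterally, which no real face allows. All
16 landmarks are placed at mesh vertices from the generating functions
(the pronasale at the local anterior maximum of the tip region), so they
lie exactly on the surface and track their vertices through every
deformation.

Growth from T0 to T1 (≈1–3 years of adolescent change) is composed of:

* **lower-face protrusion** (default 2 mm): anterior displacement with a
  smoothstep weight rising from 0 at face-frame y = −32 mm (just below
  the area4 primitives) to 1 at y = −55 mm, i.e. full at the chin;
* **nasal growth**: anterior displacement decaying as a radial Gaussian
  (σ = 10 mm) from the pronasale;
* **global forward drift**: uniform anterior translation of the whole
  face (the soft-tissue thickening seen in most growing subjects);
* **adiposity change**: signed displacement along vertex normals with
  Gaussian weights (σ = 16 mm) on the cheeks (weight-change analogue);
* **acquisition noise**: per-vertex Gaussian along vertex normals with
  exact N(0, σ) marginals (σ default 0.05 mm) and a 3 mm spatial
  correlation length. Real scanner noise is wavy rather than independent
  per vertex; an i.i.d. field at sub-millimetre mesh spacing produces
  jagged surfaces whose interlocking minima bias any closest-point
  registration, an artifact no scanner exhibits.

T1 is the deformed, independently-noised surface moved by a random rigid
misalignment (rotation 1–5°, translation up to 5 mm per axis); T0 gets
independent noise of the same σ. The inverse misalignment is recorded as
the true stable-frame transform — the synthetic stand-in for the
voxel-based cranial-base registration that serves as gold standard on
real data — together with the noise-free displacement field.

Three cohort scenarios fix the study conditions: `stable` (protrusion
U[1,3] mm only — growth confined outside area4), `contaminated` (adds
drift U[0.3,0.8] mm and cheek adiposity U[−0.5,0.5] mm, contaminating
every surface reference), and `rotation` (adds nasal growth U[1,2] mm
with a stable forehead, exposing the pitch artifact of the small
forehead-less area5). Per-subject seeds spawn from the master seed; all
runs are bit-reproducible.

### What the generator does and does not emulate

It reproduces the geometric features the pipeline's logic depends on —
identifiable anatomy for regions, growth concentrated in the middle and
lower face, a global drift, pose misalignment, correlated surface noise —
with closed forms and zero external assets. It does not attempt a
statistically realistic human shape space (no morphable model), hair,
expression, or segmentation artifacts, and T0/T1 share a mesh topology,
which real scan pairs do not. Passing tests therefore demonstrate the
correctness and the comparative behaviour of the algorithms under
controlled conditions, not clinical accuracy on real scans.

## Numerical choices and problem sizes

* Default mesh resolution ≈3,000 vertices (grid spacing ≈2.4 mm), the
  smallest size at which the 100-vertex patches stay local and pairwise
  disjoint; validation cohorts use 18 subjects, matching the study design
  the pipeline emulates.
* Duplicate-vertex merge tolerance 1e-6 mm (STL stores per-facet
  vertices); merge preserves first-appearance order.
* Ties anywhere a selection could be ambiguous resolve toward the lower
  vertex index.
* Registration accuracy at these conditions: a noise-free rigidly
  displaced copy is recovered to machine precision (≪1e-3 mm); with
  σ = 0.05 mm noise on both scans, the area4 fit recovers the true frame
  to ≈0.1–0.2 mm mean vertex displacement. This is an estimator floor,
  not a convergence failure — the two independent noise fields genuinely
  displace the global optimum, and the weakest constraint modes of a
  small reference area amplify it — and it is the quantitative face of
  the finding that larger stable references are more robust. The
  growth-contaminated whole-face reference (area1) disagrees with the
  true frame by ≈1 mm under the same conditions, a 5–7× ratio.
* The colormap export clamps at a symmetric ±2 mm by default (typical for
  facial growth figures) and records the scale in a PLY header comment.

## Known limitations

* Region-definition constants were calibrated visually on the synthetic
  face; on real data the operator should verify them anatomically (they
  are all editable in one `AreaConfig`).
* The Kolmogorov–Smirnov branch uses the Lilliefors correction; software
  that applies the uncorrected one-sample KS test to studentised data
  will report different (anti-conservative) p-values.
* MAD under-reads oblique rigid offsets by the patch-average |cos θ|
  (see above); comparisons between methods are unaffected because all
  methods share the measurement.
* Reported reproducibility covers landmark re-selection and registration
  only; on real data, segmentation error adds to it.
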