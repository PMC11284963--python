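# Methods

`femrot` measures the three-dimensional rotation of the distal femur
relative to the proximal femur between two surface scans of the same bone
(ΔFR — the femoral rotation change). This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## The measurement model

Two triangulated surfaces are given: an earlier scan `W0` and a later scan
`W12`, both in millimetres (e.g. segmented from CT 12 weeks apart, over
which a juvenile femur roughly doubles its volume). The pipeline is:

1. **Initial alignment.** `W0` is registered onto `W12` with a similarity
   transform (uniform scale, proper rotation, translation) — principal-axis
   prealignment followed by iterative closest point (ICP). Scale absorbs
   interval growth while preserving the shape of `W0`. The result is the
   size-matched `W0ᵀ`.
2. **Sectioning.** `W0ᵀ` is cut by axial fraction of its bone length:
   a proximal section (default 40%, containing head, neck and trochanters)
   and a distal section (default 15%, containing the condyles). Faces are
   kept only when all three vertices pass the axial test; fractions are
   measured along the straight long axis, not arc length.
3. **Per-section registration.** Each section is registered to the *full*
   `W12` mesh; nearest-neighbour correspondences land on the matching
   anatomy without requiring a consistent sectioning of `W12`.
4. **ΔFR extraction.** With section rotations `R_P` and `R_D`, the
   rotation change is `R_D · R_P⁻¹`, conjugated into the anatomical frame
   of `W12` (so its z-component is torsion about the shaft). `R_P` is not
   assumed to be the identity: using the relative rotation makes the
   measure independent of how the initial alignment distributed its
   residual error, and a whole-bone similarity applied to either scan
   cancels exactly. Components are reported both as extrinsic-XYZ Euler
   angles (`R = Rz·Ry·Rx` about fixed axes, matching the simulator's
   application order) and as a rotation vector; `(0, 0, 0)` means no
   rotational change.

For cross-scan comparisons against a known intervention, a growth baseline
measured on the untwisted pair is removed: `compose` mode (default)
removes it as a rotation, `decompose(R_twisted · R_baseline⁻¹)`; `subtract`
mode is literal component-wise subtraction. The two differ only at second
order for small, non-commuting angles.

### Anatomical frame

The frame derives from the principal axes of the vertex cloud (plain
covariance, not a volume-weighted inertia tensor: for uniformly meshed
surfaces the difference is negligible, and the choice is isolated in
`principal_frame`). The dominant eigenvector is the long axis. Its
proximal orientation comes from a shape cue — the extremity whose
outermost 10% vertex slab has the larger transverse centroid offset from
the axis is proximal, because the head and neck shift the proximal end
off-axis while the paired condyles straddle it — or from an explicit hint
(`--proximal-end` in the CLI). Transverse-axis signs are fixed from the
third moment of the projections so repeated calls are reproducible.

### Registration details

* **Inner solver.** Closed-form least-squares similarity (SVD of the
  cross-covariance with the determinant-sign correction); rotation always
  proper, scale optional.
* **Correspondence.** Point-to-point, source vertex to nearest target
  vertex, on a seeded uniform subsample of at most `sample_size` (default
  2000) source vertices. Deterministic given the seed, bit-reproducible.
* **Stopping.** Relative RMS change below `rms_tolerance` (default 1e-7)
  or `max_iterations` (default 100); non-convergence is reported in the
  result, not raised. With no trimming the post-fit RMS is non-increasing.
* **Scale discipline.** The prealignment scale comes from the surface-area
  ratio of the two meshes — area is nearly invariant under the bending
  and twisting deformities being measured, unlike the axial extent — and
  ICP's scale estimate is clamped to a ±5% band around a fixed anchor.
  Unconstrained similarity ICP on poorly overlapping poses can otherwise
  collapse the scale (shrinking the cloud toward the target centroid
  beats rotating it).
* **Flip handling.** A femur is coarsely two-fold symmetric about its
  shaft: in prealignment the head can masquerade as the trochanter. For
  same-bone registration the four right-handed axis assignments are ranked
  by symmetric nearest-neighbour RMS (`prealign`), which resolves the flip
  because the shapes are identical. The ΔFR pipeline instead refines the
  minimal-rotation candidate, encoding the assumption that the two scans
  arrive in grossly consistent orientation (CT scans share the scanner
  frame, so the true relative rotation is far below 90°); with
  inter-subject shape differences no surface-distance score separates the
  flip reliably, and gross input orientation is the honest disambiguator.
* **Section cascade.** A 20° tri-axial twist is a ~34° net rotation of the
  distal block — outside the convergence basin of a single ICP started at
  the identity, which stalls with the section cradled 1–2 mm off the
  surface. Sections are therefore registered coarse-to-fine over section
  sizes (distal 45% → 30% → 15%, proximal 60% → 40%): the larger sections
  overlap the deformation ramp, so their registrations land at
  intermediate rotations that walk the start point into the final basin.
  The final pose is additionally probed with ±3/6/9° nudges about the long
  axis, the ill-conditioned direction of a near-axisymmetric section; a
  probe is kept only if it strictly lowers the RMS.
* **Section scale.** The initial alignment is a compromise whose scale can
  be a few percent off when the bone deformed between scans; rigid section
  registration converts that size mismatch into a rotation bias of up to
  several degrees. Sections therefore default to similarity registration
  with scale banded ±5% around 1 (`section_with_scale=False` restores
  strictly rigid sections).
* **Subdivided registration target.** Section registrations match against
  a once midpoint-subdivided copy of `W12`: with ~2 mm vertex spacing,
  vertex-to-vertex quantization alone biased section poses by more than a
  degree; subdivision approximates point-to-surface correspondence at
  negligible cost, and original vertices are preserved so exact overlaps
  stay exact.
* **Conditioning warning.** A section whose two transverse covariance
  eigenvalues differ by less than 5% is flagged: long-axis rotation of a
  near-axisymmetric section is ill-conditioned.

### Coupled baseline and intervention measurements

Cross-subject validation subtracts two measurements (untwisted baseline,
twisted pair). The subtraction only cancels the shape-mismatch
pseudo-rotation if both measurements settle in the same convergence
context; fully independent runs occasionally settled in different local
minima, producing large corrected outliers. `run_validation` therefore
warm-starts each twisted assessment from the pair's baseline: the
baseline's initial alignment is reused verbatim (the twisted target's
proximal region is identical to the untwisted one) and the section
cascades are seeded from the baseline section poses. The registrations
still converge fully on the actual twisted target; only the starting
points are shared.

## The virtual twist (ground-truth simulator)

The twist rotates each vertex at pre-twist axial fraction `u` about a
fixed pivot (the long-axis point at the ramp start) by
`Rz(w·az)·Ry(w·ay)·Rx(w·ax)` in bone-frame axes, with weight `w` ramping
from 0 at 40% of bone length to 1 at 20% (cosine profile by default, C¹ at
both ends; linear available). Consequences, all tested:

* vertices proximal of the ramp are bit-identical;
* the distal 20% — in particular the distal 15% assessment section — is
  one rigid rotation by exactly the nominal angles, making the simulated
  deformity a well-defined ground truth;
* same-axis twists compose additively;
* with simultaneous tri-axial angles the fixed X-then-Y-then-Z application
  order is what produces the small cross-axis interference seen in
  tri-axial experiments.

The ramp saturating *below* the distal section fraction is a deliberate
choice: recovering ≈100% of a nominal angle is only possible if the
assessed section lies wholly in the rigidly rotated zone.

## The synthetic cohort

No real scan pair ships with the package, so a seeded generator emulates a
growing juvenile femur. Each bone is an implicit union of simple solids —
bowed shaft tube, offset head sphere on an angled anteverted neck,
greater-trochanter bump, two condylar lobes with epicondylar bumps and a
carved trochlear groove, and a linea aspera ridge running into the
supracondylar region — polygonized by marching cubes on a uniform grid
whose pitch is calibrated in two passes to hit a target vertex count
(default 4000; a mesh-decimation backend is deliberately not required).
Gaussian noise (default 0.1 mm, sub-voxel for 0.8 mm CT slices) is applied
along vertex normals.

The asymmetric features are not decoration: each was added because
long-axis rotation was demonstrably unidentifiable without it. Two bare
condylar spheres are rotationally slippery for point-to-point ICP; an
axisymmetric shaft leaves torsion unconstrained; and under a few percent
of shape drift the azimuth-symmetric bulk outvotes weak features, which is
why the condyle asymmetry (radii 1.10/0.92, posterior offset of the medial
condyle) is pronounced.

Growth over the interval (defaults): uniform scale 1.35 with an extra 1.08
axial stretch (volume ratio ≈ 2.7, matching a rough doubling of body
weight), relative radius jitter of 3% (shape drift), natural torsion drawn
per subject from N(3°, 2°) and applied through the same ramp machinery,
independent re-polygonization with a shifted grid (no vertex
correspondence, mirroring two independent segmentations) and fresh noise.
Cohorts add ±10% per-subject jitter on radii and lengths and ±3% on neck
angles, with per-subject seeds spawned from a master seed.

What the generator does **not** emulate: real cortical/trabecular surface
texture, segmentation artefacts, metal artefacts, growth-plate-localized
remodelling, or anatomically validated pig morphometry. Passing the
synthetic experiments therefore demonstrates the *registration method's*
accuracy under controlled shape change, noise and re-meshing — the same
logic as a contrived-ground-truth validation — not clinical accuracy on
real scans.

## Experiments and metrics

* **Verification** (same bone): each later scan against its own twisted
  copy, tri-axial `(a, a, a)` twists at 5/10/15/20° (single-axis mode
  available). Detected angles are reported in the frame the twist was
  defined in; otherwise the twist itself perturbs the principal axes of
  the target and frame estimation leaks into the comparison.
* **Validation** (cross time point and subject): every ordered pair of
  subjects crossed with every angle — `n²·|angles|` registration
  experiments (484 at n=11) — with the growth baseline computed once per
  pair, shared across angles.
* **Metrics.** Normalized detection (detected/true × 100, per axis, axes
  with zero true angle omitted); detection error (deviation of the mean
  normalized value from 100%); mean absolute error with sd; coefficient of
  variation (100·sd/mean); Bland–Altman mean difference with 1.96·sd
  limits of agreement — relative differences for verification (errors
  scale with the angle), absolute degrees for validation. Sample (n−1)
  standard deviations throughout.

Problem sizes in the shipped acceptance script: 20 seeded similarity
recovery trials, an 11-subject verification cohort, a 4-subject validation
cohort (64 records), all at 4000-vertex meshes — sizes chosen so a full
run completes in a few minutes on one core while every protocol is
exercised end to end.

## Known limitations

* The method's envelope is net deformity rotations up to roughly 25°;
  around 50° (e.g. tri-axial 30°) the whole-bone compromise alignment
  itself breaks down.
* Inputs must be grossly consistently oriented (within ~90° about the
  shaft); a quasi-symmetric bone cannot be azimuthally disambiguated from
  surface distance alone across subjects.
* Component-wise antisymmetry under swapping the two scans holds only to
  second order for tri-axial changes (the Euler decomposition of an
  inverse is not the negated triple); the matrix-level relation is exact.
* The Euler sequence is a convention; both the extrinsic-XYZ triple and
  the rotation vector are emitted, and the convention tag travels with
  every result.
* Growth correction assumes the baseline pseudo-rotation is reproducible
  between the baseline and intervention measurements; the warm-start
  coupling enforces this within the validation harness, but two scans
  acquired with grossly different segmentation protocols may violate it.
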