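# Methods

## Scope and coordinate conventions

The package measures 3D morphometry of a thoracic scoliotic spine segment
from labelled voxel volumes, compared between a neutral supine position
(NSP) and an extended supine position (ESP).  All computation happens in a
fixed right-handed world frame in millimetres: +x subject-left, +y
anterior, +z cranial; coronal = x–z, sagittal = y–z.  The loader permutes
and flips voxel axes so that the affine becomes axis-aligned with positive
steps; it trusts the file's affine and cannot detect a mislabelled world
frame.  Voxel coordinates are voxel-centre based.

Manual observer choices on real data — which levels are measured, which
vertebra is the apex, which is the neutral (rotation-reference) vertebra,
which are the Cobb end vertebrae, and which side is the curve's convexity
— are explicit inputs (manifest fields / `SubjectSpec`), not auto-detected.

## Phantom: constructive geometry and ground truth

The phantom replaces unavailable patient imaging.  Its geometry is chosen
so that every measured quantity has a closed-form truth computed *before*
voxelisation.

**Centreline.**  With segment height H (n vertebrae of height 20 mm and
discs of 5 mm), the coronal deflection is a cosine arch
x(z) = A·sin(πz/H); A is solved so the tangent tilts at the two end
vertebrae's mid-heights sum to the prescribed Cobb angle.  The sagittal
tangent angle varies linearly in z (a circular-arc-like profile), scaled
so the T4-superior / T12-inferior tilts span the prescribed kyphosis.
Under the classical projected-trace-line angle definitions used by the
measurement stages, both prescriptions are exact by construction.

**Vertebrae.**  Each body is a rigid elliptic cylinder (lateral semi-axis
16 mm, AP semi-axis 12 mm, height 20 mm) whose axis is the local
centreline tangent; endplates are the flat cylinder ends.  A circular
canal (radius 6 mm) sits 21 mm posterior to each body centre and rotates
with the body; per-vertebra canal segments extend half a disc height past
the body so the canal is continuous.

**Axial rotation.**  Rotation magnitudes follow a cosine taper: the
prescribed maximum at the apex, exactly zero at both end vertebrae.
Because "axial rotation relative to a differently tilted reference
endplate" is convention-dependent (plausible conventions disagree by up
to ~2° at a 45°/23° curve), the zero-rotation direction of each vertebra
is defined as the *geodesic transport* of the neutral vertebra's anterior
axis into that vertebra's endplate plane; the prescribed angle is applied
about the body axis on top of it.  The injected value is then exactly the
quantity the measurement defines (angle to the neutral vertebra's AP
axis, compared in a shared plane), making truth/measurement closure a
test of the pipeline rather than of a convention.

**Discs.**  Each disc fills the inter-body gap: the elliptic tube between
the two facing endplate planes.  The apical disc's coronal wedge is set
exactly to `disc_wedge_deg` by an extra coronal tilt (± half the
difference from the curvature-induced natural wedge) of its two
neighbouring vertebrae — which therefore must not be end vertebrae.  The
CoV of this wedged slab is closed-form (linear height field over an
ellipse).  The nucleus pulposus is a smaller elliptic cylinder (45% of
the disc's semi-axes, 55% of its height) whose centre is the disc's CoV
displaced `np_offset_mm` along the lateral axis toward the convexity, so
the true NP–IVD CoV distance equals the prescribed offset exactly and the
true NP mid-coronal asymmetry is zero.  NP offsets taper (cosine) over
the three apical-region discs, 1.0 at the apical disc.  A containment
check rejects parameter combinations where the nucleus would breach the
annulus or the bodies would interpenetrate.

**True EC−XC.**  For the wedged elliptic disc the analytic mid-coronal
asymmetry is 2·ū, where ū is the lateral CoV shift toward the convexity;
this is the stored truth for the IVD.

**Voxelisation.**  Centre-of-voxel membership tests, painted in the order
bodies → canal → annulus → nucleus, with overlap checks that reject
dimensionally impossible geometries.  Labels stay integral; no
anti-aliasing.  Optional surface jitter (≤ 0.5 voxel, seeded, off by
default) perturbs the membership coordinates for robustness experiments;
it is never used in recovery tests.

**Obliquity.**  By default the whole spine is tilted 3° about x and 3°
about y relative to the voxel grid.  Real acquisitions always have
scanner-vs-anatomy obliquity; a perfectly lattice-aligned apex is a
degenerate configuration in which the thin disc's voxelisation errors are
coherent (bands of whole voxel columns appear/disappear together),
shifting the measured disc CoV by up to ~0.6 mm at 1 mm voxels.  With the
obliquity the errors dither and the CoV error drops an order of
magnitude.  The truth frames carry the same rotation, so truth and
measurement remain exactly comparable.

**Cohort simulation.**  Per-subject neutral parameters are drawn from
Normal distributions at the cohort means (kyphosis 23° ± 2.6, Cobb
45° ± 7.8, apical rotation 16° ± 6.6, apical nucleus offset
4.6 mm ± 1.6), truncated to the generator's valid ranges.  The
extension-induced changes form a coupled chain — kyphosis change
N(−10°, 4°); Cobb change = 0.9 × kyphosis change + N(0, 1.8°); rotation
change = 0.78 × Cobb change + N(0, 2.5°); nucleus offset change
N(−0.9, 0.8) mm — so the cohort exhibits the three-plane coupling the
package exists to quantify (kyphosis–Cobb change correlation ≈ 0.9,
Cobb–rotation ≈ 0.6–0.8) rather than spurious independence.  The change
SDs are consistent with strongly significant paired kyphosis/Cobb effects
and a moderate rotation effect at n = 10.  The disc wedge is tied to the
coronal curve (8° at 45° Cobb, proportional otherwise) in both positions.

## Measurement stages: numerical choices

**Endplate extraction.**  The endplate surface of a body label is the
extreme voxel of every grid column along the grid axis nearest the body's
own axis (its principal direction closest to cranial) — a one-voxel-thick
height map.  On tilted bodies, columns on the downhill side terminate on
the lateral wall rather than the endplate; these are removed by iterating
a total-least-squares plane fit with one-sided trimming (points more than
one voxel on the body side of the fitted plane are dropped, up to 4
iterations).  A thin slab at the surface was rejected as an alternative:
on near-lattice-aligned bodies it selects a partial staircase ring and
biases the fitted normal by several degrees.

**Plane fitting.**  Total least squares via SVD; the normal is the
least-variance direction, oriented cranially (positive z; ties broken
toward +y, then +x).  Collinear point sets and exactly isotropic clouds
(no defined least-variance direction) are rejected with errors rather
than resolved arbitrarily.

**True axial sections.**  A section collects voxel centres within half a
slab thickness (default: half the mean voxel size, i.e. one voxel layer)
of a plane and projects them into an in-plane orthonormal basis.  For
AP-axis measurement the section plane is the endplate plane shifted 1.5
voxels *into* the body: a slab at the exact surface cuts a partial
crescent of the voxel staircase and biases the body CoV laterally by up
to ~1 mm (~3° of AP-axis error); an interior slab cuts a complete
elliptical cross-section, and rotation is constant through the rigid
body.

**AP axis.**  The line from canal CoV to body CoV (the canal is
posterior, so it points anterior).  The most anterior/posterior body
points along the axis are computed and logged as QA provenance but do not
enter the axis: extreme points are noise-sensitive on voxel masks.

**Rotation comparison.**  The test AP axis is brought into the reference
plane by the minimal rotation aligning the two section normals
(`method="transport"`), then the signed in-plane angle to the reference
axis is taken; the sign is positive toward the curve convexity and tables
report magnitudes.  Plain orthogonal projection is available
(`method="projection"`) but compresses a rotation ρ by ≈ (1 − cos τ)·ρ
for endplates tilted τ from the reference — about −1.2° at a 45°/23°
curve apex — so it is not the default.  Per-vertebra rotation is the mean
of the two endplate rotations; the peri-apical mean covers exactly the
apex ± 2 vertebrae.

**Cobb / kyphosis.**  Angle between the two endplate planes' trace lines
after projection onto the coronal (respectively sagittal) view, folded to
[0°, 90°]; symmetric in its arguments; an endplate normal orthogonal to
the view is a degenerate-projection error.

**Disc metrics.**  IVD = NP ∪ AF (overlap is a segmentation error).  CoV
distance is the full 3D Euclidean distance between the two CoVs.  The
mid-coronal plane is the one-voxel coronal slab through the structure's
*own* CoV; EC and XC are 3D Euclidean distances from the CoV to the
extreme lateral member points in the slab (a pure-lateral x-component
variant is emitted alongside).  Extreme-point ties are broken
deterministically toward the CoV's axial height.  Mirroring a volume
across the sagittal midplane negates EC−XC exactly when the convexity
flag is held fixed, and preserves it when the flag swaps with the
anatomy.

**Statistics.**  Paired t (two-sided, df = n−1; identical to a one-sample
t on the differences), Pearson r with the t-transform p value, Bonferroni
control over the four curve outcomes (α/k; k = 4 gives 0.0125) with an
alternative fixed p < 0.01 flag printed alongside — the two conventions
coexist in practice and the report surfaces both.  Confidence intervals
use the t distribution with df = n−1.  Display rounding: angles to whole
degrees, distances to 0.1 mm, Δ% to whole percent; raw values are kept in
the returned objects.  Zero-variance differences (t undefined) and
zero-variance correlation inputs raise errors rather than returning NaN.
Normality is inspected via an exported Q–Q plot, not gated on.

## Problem sizes

Recovery tests run on 1 mm phantoms (~1.5M voxels, ~1 s to generate and
measure).  The simulated cohort uses 10 subject pairs at 1.5 mm voxels —
measurement noise at 1.5 mm is ≲ 0.5°, negligible against the 4° change
SDs — and the paired-t power assessment runs 200 Monte-Carlo replicates
at the parameter level with the same change distributions, since the
voxel-measurement layer contributes no appreciable extra variance.

## What the phantom does and does not establish

The phantom shares real data's voxel quantisation, the full measurement
chain, and clinically realistic deformity magnitudes, so passing recovery
tests establishes the correctness and numerical stability of the
geometry and statistics.  It does **not** emulate: realistic vertebral
shape (pedicles, processes, endplate concavity), the rib cage,
segmentation errors beyond optional surface jitter, intensity-based
segmentation at all (the pipeline consumes finished labels), nucleus
*shape* deformation (the phantom's NP is symmetric, so its true EC−XC is
zero, whereas deformed nuclei in patients have nonzero asymmetry), or
inter-observer variability in the manual inputs.  Accuracy on real
segmentations is therefore bounded below by, not equal to, phantom
accuracy.

## Known limitations

* The neutral (reference) vertebra is a manifest input; automatic
  detection of the first distal neutrally rotated vertebra is future
  work.
* Kyphosis assumes the measured segment spans T4–T12; other spans reuse
  the same endplate construction but the name is then a misnomer.
* EC/XC are measured against each structure's own CoV; measuring the NP
  against the IVD's CoV is a documented alternative not implemented.
* Whole-spine sagittal balance, rib-cage metrics, disc-degeneration
  grading and radiograph-based measurements are out of scope.
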