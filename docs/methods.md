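# Methods

## Model and assumptions

The spine segment is modelled as a chain of rigid vertebrae. Each vertebra
carries a center of mass (CoM, mm), unit normals of its superior and
inferior endplates (n_sup pointing cranially, n_inf caudally), and a rigid
pose. Intervertebral discs and soft tissue are not modelled: the package
computes angular alignment geometry, not biomechanics, which is what makes
real-time feedback feasible.

Coordinates follow the LAI scan convention — x = left, y = anterior,
z = inferior — treated as a right-handed algebraic frame. All analysis is
per anatomical plane:

* sagittal: in-plane coordinates (u, v) = (anterior, inferior)
* coronal: (u, v) = (left, inferior)

so v is the cranio-caudal "height", increasing caudally. Projected
direction vectors are renormalised in-plane so every offset expressed along
them is a true in-plane distance; a direction perpendicular to the plane
(projection below 1e-6 in norm) is a hard `DegenerateProjectionError`
because it carries no in-plane information.

Exactly two vertebrae per estimation span are tracked (the minimum a curve
with two endpoints needs). The superior tracked vertebra VR₀ is the fixed
reference: tracker poses enter only through relative transforms
T(VR₀)⁻¹·T(VRᵢ), composed against the relative pose observed at
registration. Consequently any rigid motion common to all tracker poses
(patient repositioning, tracker re-mounting) cancels identically — the
gauge-invariance tests verify this to 1e-6° end to end. Corrections are
always composed onto the registration-time snapshot, never onto the
previous frame, so repeated updates cannot accumulate drift.

## Estimation pipeline

**Chain fractions.** %dᵢ is the cumulative polyline distance from CM₀ to
CMᵢ along consecutive CT-time CoMs divided by the total chain length
(i = 1…n−2). The straight-line alternative (distance from CM₀ projected on
the chord) is implemented behind `mode="straight"`; chain is the default
because it preserves ordering on curved spines and degrades gracefully as
curvature grows.

**Curve estimation.** The "intersect" decision of CE_EN is made on *rays*,
not infinite lines: the caudal ray from CM₀ along the projected n_inf and
the cranial ray from CM₋₁ along the projected n_sup must be non-parallel
(|2-D cross| > 1e-9) with both ray parameters > 0. Infinite-line
intersection would fire almost always; rays restrict it to the anatomically
meaningful concave-side crossing. Parallel or anti-parallel normals (the
straight spine) always take the 4-control-point branch, which then
reproduces the straight segment exactly. An intersection far beyond the
inferior vertebra (very large positive parameter) is still accepted; this
policy is a documented choice, not derived from data.

**Root finding.** Curve/line intersection and point-at-height both reduce to
real roots of a scalar polynomial given in Bernstein form (degree ≤ n−1).
The coefficients are converted to the power basis and solved with
`numpy.roots`; leading coefficients that are zero up to round-off *relative
to the coefficient scale* are trimmed first (a spurious tiny leading term
ill-conditions the companion matrix), and every kept root is polished with
up to eight Newton steps, giving parameters accurate to ~1e-12 and residual
distances well below the 1e-7 contract the placement code asserts. An
identically zero polynomial (curve lying on the line) returns the hint.

**Multiple roots.** `curve_point_at_height` takes the smallest t (most
cranial crossing; the curve's height can be non-monotone for extreme "V"
shapes, and cranial-first is our documented tie-break).
`intersect_curve_line` takes the root nearest the caller's hint, which is
the vertebra's chain fraction — this preserves cranial→caudal ordering, a
property checked on 500 random smooth phantoms.

**Perpendicular placement.** PE_P never forms the textbook slope
m_p = −1/m: perpendicularity is a 90° rotation of the chord direction
vector, so vertical and horizontal chords need no special-casing (the
slope/intercept view exists on `Line2D` for documentation parity only).
When a perpendicular misses the curve entirely, the default policy places
the vertebra at the nearest curve point, flags it, and logs a warning —
intraoperative streams must degrade gracefully — while `strict=True` turns
this into an error.

**Orientation.** The alignment formulas give only angle magnitudes
(arccos of a normalised dot product); a rotation needs a direction, and the
sign of the 2-D cross product of (reference, target) is the unique
orientation-consistent choice, with counterclockwise positive in each
plane's (u, v) frame. Anti-parallel vectors report +180°. For OC_IVN the
post-condition holds by construction: rotating the vertebra in-plane by
θ = ∠(vᵢ, tᵢ) makes its intermediate endplate vector parallel to the local
tangent (verified to 1e-6° in the tests). For OC_STV the correction turns
the vertebra's registration-time orientation by the curve's local deviation
from the superior tangent; both methods coincide when every intermediate
vector initially equals the tangent direction at CM₀.

**Combining the two planes.** The per-plane angles form the rotation vector
r = [θ_s, θ_c_axis, 0] about the LAI axes, exponentiated as a single
axis-angle rotation (order-free and symmetric in the two planes; the fixed
x-then-y Euler alternative is available via
`rotation_convention="euler_xy"` and differs at O(θ²), about 3e-4 rad for
two 1° angles). One sign subtlety is ours to fix: with coronal in-plane
coordinates (left, inferior), a counterclockwise in-plane rotation is a
*negative* rotation about the +anterior axis in the right-handed LAI frame,
so the coronal component of r is the negative of the in-plane coronal
angle. The 3-D CoM is reassembled from the two planar estimates — sagittal
supplies (anterior, inferior), coronal (left, inferior) — and the
duplicated inferior coordinate is averaged, with discrepancies logged
(the two-plane analysis is independent by design; averaging is the
symmetric reconciliation).

**Feedback metrics.** The pairwise endplate angle is the acute angle in
[0°, 90°] between the projected endplate *lines* (superior endplate of the
superior vertebra, inferior endplate of the inferior one) — a Cobb-style
magnitude; a signed variant is exposed for direction-of-correction use.
Δ = simulated − baseline (positive = angle increased intraoperatively).
RMSE uses the population mean over the vertebra pairs (divisor = number of
pairs, 6 for a 4-vertebra segment).

## Method matrix

All evaluation logic keys on the explicit (curve, position, orientation)
triple. The M-labels are display names: M1 = (EN, H, STV),
M2 = (ENIP, H, STV), M3 = (EN, P, STV), M4 = (ENIP, P, STV),
M5 = (EN, P, IVN), M6 = (ENIP, P, IVN), M7 = (EN, H, IVN),
M8 = (ENIP, H, IVN). This mapping is reconstructed from the constraints
that M5–M8 use IVN, M8 = ENIP + PE_H + IVN, and M6 uses PE_P; it is an
assumption of the package, which is why the labels are sugar and the triple
is authoritative.

## Synthetic phantoms

`spinecurve.phantom` generates segments with exact ground truth. Defaults
mirror the ex vivo validation configuration: 6 vertebrae — 4 intermediates
between the 2 tracked ends — at 30 mm CoM spacing (a typical lumbar
inter-vertebral distance). Profiles:

* **straight** — level endplates, zero angles everywhere (the identity
  fixture);
* **arc** — a single bend of given total angle; vertebra orientations rotate
  in equal increments and gap directions use the mid-gap angle, reproducing
  circular-arc chord geometry; endplates are tangent-aligned, optionally
  with a fixed per-vertebra wedge;
* **v** — two straight sub-chains meeting at a wedged apex, the shape a
  posterior vertebral resection produces in a spine whose sub-segments
  cannot themselves bend.

`simulate_correction` opens a wedge at an apex vertebra of an existing
truth: the superior sub-chain stays put, the apex's inferior endplate and
everything below rotate rigidly about the apex CoM, and the function
returns both the post-event ground truth and the tracker poses the tracked
pair would report — exactly the input the pipeline sees in surgery.
Gaussian position noise (mm) and normal-direction noise (degrees, random
axis) perturb only the *observable* segment, never the returned truth; one
seeded generator drives all randomness.

What the phantoms do **not** emulate: segmentation and registration error
of a real CT→tracker chain, marker occlusion and jitter, disc deformation,
and vertebra shape change at the osteotomy site. Passing the recovery tests
therefore demonstrates correctness of the geometry and estimation logic
under the stated assumptions, not clinical accuracy.

## Validation dataset

`spinecurve.poc_dataset` embeds the printed measurement rows of the ex vivo
porcine experiment (4 evaluable vertebrae L1–L4, references on L1 and L4,
Ponte osteotomy at L3): manual CT assessments, direct system measurements,
and the eight estimation methods, pre- and postoperative, six vertebra
pairs per plane, with the published RMSE per row. The tests recompute every
RMSE from its own angle row (reproducing the published value within the
0.01° two-decimal rounding for 39 of 40 cells; the remaining cell and two
published extrema are internally inconsistent in the source data and the
corresponding tests document the recomputed values: 0.695 vs 0.71, 8.03 vs
8.11, 1.06 vs 1.11).

## Problem sizes and determinism

The pipeline is closed-form plus low-degree polynomial root finding; a full
8-method evaluation of a 6-vertebra segment takes milliseconds, so tests
and the acceptance script run phantom studies at the study's native sizes
(6 vertebrae, 8 methods, a few hundred property-test repetitions). There is
no randomness anywhere in the estimation path — identical inputs give
bit-identical reports; randomness exists only in the phantom noise model,
behind a seed.

## Known limitations

* A "V"-shaped spine (post-osteotomy) violates the smooth-curve assumption;
  sagittal errors grow to several degrees while the unaffected coronal
  plane stays exact. This is inherent to the approach, reproduced by the
  V-phantom tests, and surfaced rather than hidden.
* The intervened vertebra's own shape change is not modelled; flagging a
  vertebra as `intervened` logs an audit warning but computes with
  registration geometry.
* Axial-plane rotation is out of scope (no standardized angular metric).
* Spans with more than two tracked vertebrae are handled as independent
  consecutive tracked pairs, not jointly.
* cSVA/SVA and spinopelvic distance parameters are deliberately excluded;
  the feedback surface is pairwise endplate angles only.
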