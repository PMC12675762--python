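# spinecurve

Radiation-free intraoperative spinal-alignment estimation from two tracked
vertebrae.

During deformity-correction surgery (scoliosis, kyphosis/lordosis repair),
surgeons need quantitative feedback on the spine's curvature, but today that
means fluoroscopy or intraoperative CT — radiation, workflow interruption,
and still mostly visual judgement. `spinecurve` implements the geometric
core of a navigation-style decision-support approach: attach optical-tracker
rigid bodies to just **two** vertebrae of a segment, register them to the
preoperative CT once, and from then on estimate the whole segment's shape
and report Cobb-style endplate angles in real time, with no imaging in the
loop.

The package is aimed at computer-assisted-surgery researchers and navigation
engineers: it is the algorithmic layer (geometry, estimation, metrics,
synthetic validation phantoms), not a tracker driver or a 3-D viewer.

## Method

All computation is per anatomical plane (sagittal and coronal), in the LAI
scan convention (x = left, y = anterior, z = inferior). For a segment of
*n* vertebrae with CoMs CM₀…CM₋₁ (superior tracked vertebra VR₀ held fixed
as the reference frame; tracker poses enter through
T = T(VR₀)⁻¹ · T(VRᵢ), so common patient motion cancels):

1. **Curve estimation** — a Bézier curve C(t) through the projected tracked
   CoMs. *CE_EN* uses the tracked endplate normals: if the ray from CM₀
   along its inferior-endplate normal meets the ray from CM₋₁ along its
   superior-endplate normal (both ray parameters positive), the intersection
   is the middle control point of a quadratic; otherwise four equally spaced
   control points offset by d_pos/4 along the normals are used. *CE_ENIP*
   adds the CT-time spacing: one control point per vertebra, laid out along
   the endpoint normals at the chain fractions %dᵢ of the tracked distance
   d_pos (middle vertebra: midpoint of the two candidates).
2. **Position estimation** — intermediate CoMs are placed on C(t) either at
   the height fractions v₀ + %dᵢ·h_t (*PE_H*) or at the intersections of
   C(t) with perpendiculars to the tracked chord at %dᵢ·d_pos (*PE_P*).
3. **Orientation correction** — each intermediate vertebra is rotated by the
   signed angle θ = ∠(ref, C′(tᵢ)), where the reference is the curve tangent
   at VR₀ (*OC_STV*) or the vertebra's own intermediate endplate vector
   vᵢ = (n_inf − n_sup)/2 (*OC_IVN*); magnitudes follow
   arccos(ref·t / |ref||t|), signs follow the 2-D cross product. The
   sagittal and coronal angles are combined into one 3-D rotation (rotation-
   vector exponential of [θ_s, θ_c, 0]) applied to the registration-time
   orientation.
4. **Feedback** — for every vertebra pair, the acute angle between the
   superior endplate of the superior vertebra and the inferior endplate of
   the inferior vertebra, as Baseline / Simulated / Δ tables per plane,
   plus RMSE and min/max absolute error against a reference assessment.

The 2×2×2 combinations form the evaluation methods **M1–M8** (M8 =
ENIP + PE_H + IVN, the most accurate combination in the ex vivo porcine
validation whose printed measurements ship with the package as a fixture).

## Worked example

Generate a straight 6-vertebra phantom, simulate a 20° wedge osteotomy at
V4 (the tracker reports only the motion of V1 and V6), and estimate the
full segment with method M8:

```bash
$ cat spec.json
{"n_vertebrae": 6, "spacing": 30.0, "profile": "straight", "seed": 1,
 "correction": {"apex": "V4", "wedge_sagittal_deg": 20.0}}

$ spinecurve phantom spec.json --out run
wrote run/segment.json, run/poses.csv, run/truth.json

$ spinecurve estimate run/segment.json run/poses.csv --method M8 --out run
[sagittal]
 pair  baseline_deg  simulated_deg  delta_deg
V1-V2           0.0           0.59       0.59
V1-V3           0.0           3.49       3.49
V1-V4           0.0           9.10       9.10
V1-V5           0.0          16.05      16.05
V1-V6           0.0          20.00      20.00
...
[coronal]
 pair  baseline_deg  simulated_deg  delta_deg
V1-V2           0.0            0.0        0.0
...
```

The tracked pair V1–V6 reads exactly the simulated 20° wedge (it is
measured, not estimated); the intermediate pairs show how the smooth-curve
assumption distributes that correction. Scoring against the phantom's
ground truth:

```bash
$ spinecurve evaluate --report run/report.json --truth run/truth.json
method    plane  rmse_deg  min_abs_deg  max_abs_deg
    M8 sagittal  7.536776 2.172955e-08    14.396727
    M8  coronal  0.000000 0.000000e+00     0.000000
```

The sagittal RMSE is large because the true post-osteotomy shape is a "V"
with straight sub-chains — a shape a smooth Bézier curve cannot represent —
while the coronal plane, where nothing moved, stays exact. This reproduces
the failure mode observed in the ex vivo experiment. On smooth-arc phantoms
(≤ 30° total curvature) the best method recovers intermediate CoMs within
1% of the tracked distance and pairwise angles with RMSE ≈ 0.1°.

`spinecurve evaluate --poc-fixture` recomputes every RMSE of the embedded
porcine dataset from its printed angle rows and reports PASS/FAIL per cell
at 0.01°.

## Layout

| module | contents |
| --- | --- |
| `spinecurve.geometry` | Bézier curves, line/curve intersection, signed angles, plane projections, rigid transforms |
| `spinecurve.segment` | Vertebra / SpineSegment model, chain fractions, planar views, tracked-pose updates |
| `spinecurve.curve_estimation` | CE_EN and CE_ENIP control-point constructions |
| `spinecurve.position_estimation` | PE_H and PE_P placement |
| `spinecurve.orientation` | OC_STV and OC_IVN corrections; 3-D reassembly |
| `spinecurve.metrics` | endplate angles, Baseline/Simulated/Δ tables, RMSE, extrema |
| `spinecurve.pipeline` | method matrix M1–M8, end-to-end runner, evaluation |
| `spinecurve.phantom` | synthetic phantoms with ground truth; simulated osteotomy |
| `spinecurve.poc_dataset` | embedded porcine-study measurement rows |
| `spinecurve.cli` | `spinecurve phantom / estimate / evaluate / methods` |

See `docs/methods.md` for the modelling assumptions, conventions, and known
limitations.
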