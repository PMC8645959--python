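# Methods

`spinecouple` couples a lumped-parameter finite-element (FE) model of the
thoracolumbar spine (T10–pelvis) with an inverse-static musculoskeletal (MSK)
model sharing the same synthetic anatomy, to compare pedicle-screw and rod
stresses under two loading philosophies:

* **simplified loading** — a pure moment of 7.5 N·m applied at the T10 upper
  endplate, the standard protocol of in vitro and computational implant
  testing (no compressive load);
* **realistic loading** — concentrated muscle forces at every level from T10
  to the pelvis, obtained by static optimization for the same motion, plus
  trunk and upper-body weight.

The pipeline has three stages. Stage A solves the FE model under the pure
moment and extracts per-joint ranges of motion (ROM). Stage B imposes those
rotations on the MSK model, computes the net moment muscles must supply at
every intervertebral cut, and resolves the muscle redundancy. Stage C
re-solves the FE model loaded by the recruited muscle forces, the T10
boundary loads, and the MSK-predicted T10 translation. Consistency between
the two loading modes is then quantified (per-joint ROM differences, T10
reaction-moment agreement) and the implant stresses are compared.

## Synthetic anatomy

The generator stacks nine rigid bodies (T10–L5 vertebrae and the sacrum) on a
fixed pelvis. Per-joint sagittal wedge angles impose a mild standing
curvature (lumbar lordosis ≈ 30°, low-thoracic kyphosis, sacral slope 20°);
the default vertebral body height is 28 mm with 10 mm discs. Pedicle entry
points sit 40 mm posterior and ±18 mm lateral of each body centre, at the
facet/transverse-process junction. The geometry is exactly sagittally
symmetric and bitwise deterministic for a given configuration.

Nine bilateral muscle groups are generated: transversus, spinalis,
semispinalis, erector spinae, obliquus internus, obliquus externus, psoas
major, multifidi, and quadratus lumborum — 33 fascicles per side. Fascicles
are straight lines between body-fixed attachments; the abdominal groups
(obliques, transversus) carry one pelvis-fixed via point on the abdominal
wall (≈ 70–85 mm anterior of the spine), a frictionless redirection that
gives them physiological flexion lever arms instead of chords through the
vertebral bodies. Maximum forces follow f_max = PCSA × specific tension
(default 90 N/cm², PCSA 1.5–4 cm² per slip). A construction-time check
guarantees that every intervertebral joint is crossed by fascicles with
opposing moment arms about both the flexion–extension and lateral-bending
axes; a violation raises a coverage error naming joint and axis.

## FE model

Vertebrae are rigid 6-DOF nodes. Each disc (with facets and capsules) is a
generalized bushing: a diagonal rotational stiffness — default
(220, 170, 300) × 10³ N·mm/rad about the lateral, flexion and axial axes,
×1.3 at the thoracic levels — and a diagonal translational stiffness of
(500, 500, 2500) N/mm, both expressed in the caudal body's frame. Defaults
sit at the rigid end of the in vitro range, yielding per-level ROMs of
roughly 2–2.5° at 7.5 N·m; this deliberately represents a stiff specimen and
keeps the fused instrumented levels in the "negligible motion" regime. The
sacroiliac joints are modelled very stiff (10⁷ N·mm/rad, 5000 N/mm), in line
with the sub-degree mobility of the SIJ. Interspinous, anterior longitudinal
and intertransverse ligaments are tension-only piecewise-linear springs with
1.5 mm slack; they are the model's only nonlinearity and are resolved by
Newton iteration on the tension state (tolerance 10⁻⁶ N + 10⁻⁸·‖load‖,
50 iterations, abort after three consecutive residual increases). The pelvis
(acetabula) is fully fixed.

The L1–L5 construct consists of two 5.5 mm titanium rods (E = 110 GPa,
ν = 0.3) and ten 6 mm × 45 mm pedicle screws. Each screw head shares a node
with the rod (rigid head–rod connection) 8 mm posterior of the pedicle entry
along the screw axis (15° medial angulation); the shank is anchored by a
rigid tie at the entry point, representing bone purchase along the thread.
Rods and screws are 2-node Euler–Bernoulli beams (two rod elements per
inter-screw span). Section stresses are recovered as
σ = |N|/A + ‖M_b‖(d/2)/I and τ = |T|(d/2)/J (transverse shear neglected,
standard for slender implant beams), combined as √(σ² + 3τ²), maximized over
element ends per component.

## MSK stage

Joint rotational stiffnesses are calibrated per motion direction: for each
simulated movement, a pure-moment FE solve at 7.5 N·m gives the per-joint
rotation and the MSK stiffness is the directional secant k = M/θ about the
motion axis (off-axis coupling discarded; the stiffness does not account for
compressive loading). Directional secants are required because tension-only
ligaments make the FE moment–rotation behaviour asymmetric. Fused levels are
calibrated on the instrumented FE and acquire secants of ~5.7 × 10⁶ N·mm/rad;
they are imposed with their (sub-0.1°) instrumented stage-A rotations rather
than hard zero-rotation constraints, which makes the full moment transmission
across the fused block explicit in the recruitment instead of leaving it
statically indeterminate. A joint that does not rotate at all falls back to
a configurable rigid ceiling (10⁶ N·mm/deg) with a logged warning.

Inverse statics: the net muscle moment at each intervertebral cut equals the
passive spring moment k·θ minus the moment of the gravity loads above the
cut. The sacroiliac cuts carry no recruitment constraint — through the closed
pelvic ring their moments are carried by joint constraint forces — so the
sacroiliac consistency between loading modes is an emergent outcome, not an
enforced one.

Gravity acts only in the realistic mode (the simplified mode is deliberately
a pure moment without compressive load): 1.5 kg trunk slices at each
vertebral body and 22 kg of head/arms/upper thorax entering at the T10
boundary, its centre of mass 120 mm above the T10 centre. Load points are
displaced into the imposed posture by the rigid-chain kinematics (so flexion
carries the upper-body weight anteriorly), with the identical rule used when
building the stage-C FE load set — the hand-off is exactly consistent.

Recruitment solves min Σ (fᵢ/f_max,i)³ subject to 3-axis moment equilibrium
at every cut and fᵢ ≥ 0 (exponent configurable, > 1 for uniqueness). The
implementation uses an LP feasibility pass, an SLSQP solve started from the
min-norm feasible point, and an active-set KKT Newton polish to machine
precision. Every solution must pass an independent certificate — brute-force
re-summation of fascicle moments at every cut — to 10⁻⁶ relative.

The T10 translation handed to stage C is predicted by force-dependent
kinematics: rigid-chain forward kinematics of the imposed rotations plus the
translational joint deflections under the recruited loads. The deflections
are evaluated with the shared-anatomy lumped compliance (a load-controlled
solve of the same model, free at T10). A rigid-chain prediction alone is
inconsistent with the compliant FE under several hundred newtons of muscle
compression: the prescribed-translation constraint then develops forces that
corrupt every cut moment. With the compliant prediction the constraint force
vanishes and the T10-level reaction-moment comparison between the MSK and FE
models agrees to solver precision.

## What the consistency checks show

Because the recruitment enforces the cut moments exactly and the translation
hand-off is compliance-consistent, the remaining simplified-vs-realistic ROM
differences measure the genuinely un-modelled couplings: the ligament state
changes under compression, the force–rotation coupling of the instrumented
levels (compression shuttling between the anterior disc and the posterior
rods), and the unconstrained sacroiliac moments. On the default model these
stay within the configured bounds (0.7° intact, 0.3° instrumented, 3.5% T10
moment), while the peak screw and rod von Mises stresses are higher under
realistic loading for all four motions — the compressive muscle and body
weight load paths through the construct that pure moments omit.

## Synthetic data caveats

The generator emulates the *roles* of an anatomical surface-model-derived
geometry and a validated thoracolumbar muscle architecture; attachment
coordinates, fascicle counts, PCSA values, joint stiffnesses and ligament
curves are plausible engineering defaults, not subject-specific data.
Passing tests therefore demonstrate the correctness and internal consistency
of the coupling machinery — equilibrium, calibration round-trips, symmetry,
analytic stress recovery — not the clinical accuracy of any particular
stress magnitude. Absolute implant stresses depend strongly on the construct
anchorage idealization (rigid entry-point ties) and on the lumped disc
stiffnesses; only the simplified-vs-realistic *contrast* is the designed
output. Axial rotation is supported under simplified loading only and is not
carried through the coupling.

## Numerical choices

* Linearized (small-rotation) kinematics throughout; rotations stay ≤ ~3°
  per level, and an inverse-statics guard rejects imposed rotations > 30°.
* Rigid couplings by master–slave elimination (exact), dense Cholesky solves
  (the models have < 400 DOF).
* ROM extraction: projection of the relative rotation vector onto the
  motion's moment axis, in degrees; flexion positive under a flexion moment.
* Fused-level ROM threshold 0.1°; consistency bounds and the 7.5 N·m working
  moment are configuration values.
* Reports are written with 9-significant-digit formatting so repeated runs
  are byte-identical; the muscle-force hand-off CSV round-trips bit-exactly.
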