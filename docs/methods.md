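# Methods

## Scope and modeling idea

`footmech` is a desk-scale, quasi-static model of the loaded foot built to
study spring-ligament failure (adult-acquired flatfoot) and its surgical
reconstruction.  Bones are rigid; all soft tissue is reduced to two
ingredient types — tension-only line elements and compression-only
elastic-foundation contact — and equilibrium is found by minimizing the
total potential energy over the rigid-body coordinates.  The model trades
absolute fidelity (it is not subject-specific and carries no deformable
continuum) for a fully scriptable, reproducible pipeline in which every
scenario of the study — intact, attenuated ("flatfoot"), and four graft
routings — runs in seconds to minutes.

## Segments and constraints

Twenty-eight bones are grouped into six rigid segments: tibia+fibula,
talus, calcaneus, navicular, cuboid, and a fused forefoot (three
cuneiforms, five metatarsals, fourteen phalanges).  The grouping keeps the
articulations the study measures (tibiotalar, subtalar, talonavicular,
calcaneocuboid) independent while collapsing the rays the study does not.
Each free segment carries 3 translations (mm) and 3 exponential-map
rotations (rad) about its build-pose centroid.  The tibia+fibula segment is
constrained to vertical travel only — a loading-rig condition — and carries
the axial load (default 680 N, body weight of the modeled adult).  The
ground plane is the fixed body.

## Constitutive laws

* Exponential tension law `T(eps) = a (e^(b eps) - 1)` for the eight
  tibial/fibular ligaments (per-ligament `a` [N], `b` [-] from the packaged
  table); engineering strain, tension-only.
* Hindfoot/midfoot ligaments reuse the anterior-talofibular parameters with
  the force scale `a` multiplied by the ratio of the ligament's
  cross-sectional area to the 62.85 mm^2 reference.  Scaling `a` (not `b`)
  makes force at fixed strain proportional to area — the standard
  mechanical reading.  Forces derive from the areas; the shipped table also
  carries the printed (rounded) ratio column, whose superomedial
  calcaneonavicular entry (2.560) differs from the recomputed 2.562 at the
  third decimal and is flagged as a rounding exception by `check_tables`.
* Linear law `T = k dL` for the tibionavicular ligament (39.1 N/mm),
  plantar fascia (203.3 N/mm) and the long and short plantar ligaments
  (75.9 N/mm each; the packaged table's single long/short row expands into
  two elements).
* In-situ strain: 4% for every exponential-law ligament, applied by slack
  length calibration `L_slack = L_build / 1.04`, giving a few newtons of
  pretension per ligament in the neutral pose.  The linear-law elements are
  assembled at slack length: their stiffnesses are of order 100 N/mm over
  100–200 mm spans, so a blanket 4% strain would preload the arch with a
  non-physiological ~1.5 kN and buckle it upward at zero load.
* Graft: peroneus longus tendon, 37 mm^2, E = 2769 MPa, tension-only
  linear with axial stiffness `E A / L_slack` per bone-to-bone span.
* Muscles: constant-force routed elements (seven tendons with frictionless
  via points).  The default activation is zero — see Design decisions.

## Contact

Each articulation is a set of patch points (with tributary areas) riding
one segment against a support surface (plane, sphere or cylinder) fixed to
the mating segment; local pressure follows a compression-only foundation:

* cartilage: linear Winkler reduction of a confined layer,
  `k_f = E (1-nu) / ((1+nu)(1-2nu) t)` with E = 10 MPa, nu = 0.45 and
  t = 1 mm per facing side combined in series (k_f ≈ 19 MPa/mm);
* plantar pads: exponential strain-stiffening soft tissue,
  `p = p0 (e^(delta/d0) - 1)` with p0 = 0.06 MPa, d0 = 1.2 mm, giving
  millimetre-scale pad compression under body weight.

Contact is frictionless everywhere (mu = 0): forces act along the current
surface normals only.

Joint congruence carries the moments that a frictionless point-contact
reduction would otherwise lose, and the patch shapes encode it explicitly:
a deep mortise arc at the tibiotalar trochlea (anterior/posterior plafond
walls resist anteroposterior sliding), a convex cylindrical posterior
subtalar facet (locks sliding, leaves inversion/eversion to the
ligaments), a two-sphere ("ovoid") talonavicular head with a dorsal
talar-neck rim stop (~2 mm clearance) that bounds midfoot sag the way the
dorsal joint margin does, a two-sphere calcaneocuboid saddle with a
transverse common axis (locks abduction of the lateral column), mortised
naviculocuneiform and cuboid–metatarsal facets (plane plus socket plus
dorsal edge stops), a small cubonavicular facet (transverse midfoot
torsion), and a sinus-tarsi stop with build clearance.  These choices were
driven by stability analysis of the assembled model: each missing
congruence showed up as a zero- or negative-stiffness mode (navicular
spin, forefoot transverse slide, midfoot twist, hindfoot skate) that let
the load run away from the physiological equilibrium.

## Synthetic geometry

No subject scan is shipped; the generator produces a canonical adult right
foot (foot length 250 mm, navicular height 45 mm) as named landmarks in a
+X-anterior/+Y-medial/+Z-up frame with the ground at Z = 0.  The template
is aligned by construction: talar and first-metatarsal axes share one
direction and the tibial and calcaneal coronal axes are parallel, so all
three radiographic angles measure zero in the build pose (the intact
condition defines angle zero).  Parameters: `foot_length`, `arch_height`
(vertical rescale), `scale` (similarity), `hindfoot_alignment` (coronal
calcaneal pre-tilt), and seeded Gaussian landmark jitter
(`perturbation_sd`) for robustness studies.  Coordinates are
order-of-magnitude anatomical, documented in the source; no claim of
subject fidelity is made.  Graft tunnel landmarks (navicular dorsal and
plantar exits, anterior and posterior calcaneal holes with medial/lateral
exits, the tibial attachment, the distal peroneus longus attachment)
follow the published clinical approaches in approximate position.

What passing tests on this generator do and do not show: they demonstrate
that the mechanical pathway — attenuation to deformity to graft correction
— behaves in the clinically reported directions on a plausible skeleton;
they do not validate absolute angles or pressures for any real foot.

## Scenarios

* Flatfoot: the force scales of exactly {superomedial and inferior
  calcaneonavicular, anterior/posterior tibiotalar, tibiocalcaneal,
  tibionavicular, long plantar, short plantar, plantar fascia} are
  multiplied by the attenuation factor (default 0.5).  The plantar
  calcaneocuboid ligament of the area-scaled table is a separate element
  and is left untouched.
* Reconstructions: ISLR (navicular to calcaneus), ASLR (two limbs:
  anterior calcaneal hole to plantar navicular, dorsal navicular to
  posterior calcaneus), CSILR (ISLR limb plus navicular-to-tibia limb) and
  CSPLR (one continuous routing: distal peroneus longus attachment through
  the anterior calcaneal tunnel, back through the posterior tunnel, then
  dorsal-to-plantar through the navicular).  The graft is tied wherever it
  enters a bone tunnel, so each limb is split into its bone-to-bone spans
  and each span acts as an independent elastic segment; spans inside one
  bone are inert.  With frictionless through-tunnel sliding instead, the
  CSPLR leg length changes cancel along the single element and the
  construct is mechanically blind to the deformity — unable to reproduce
  even the qualitative correction ordering — so the tied reading (the
  natural finite-element realization) is used.
* Graft slack: each span's slack length is its routed length at the
  *intact loaded* equilibrium (zero surgical pretension on top).  This
  models a graft tensioned to restore the normal weight-bearing
  relationships, and makes all spans engage exactly when the foot deviates
  from that state.  The peroneus longus muscle element is removed in
  reconstruction scenarios (graft donor); both choices are configurable.

## Solver

Energy terms: exact integrals of the element laws (for the exponential law
`L0 a (expm1(b eps)/b - eps)`), foundation energies per patch point, a
constant-force work potential for muscles, and the external load
potential.  Gradients are analytic (SO(3) left-Jacobian mapping for the
rotation coordinates) and verified against central differences.

Because every tie is tension-only and every contact one-sided, the load
potential is unbounded below far from the assembled configuration: the
physical equilibrium is a local minimum, and the solver is built to stay
in its basin.  The axial load ramps in warm-started increments (default 6);
each increment is minimized by a trust-region damped-Newton method on a
finite-difference Hessian of the analytic gradient (eigenvalue-shifted,
rotations scaled by a 100-mm characteristic length, energy-decrease
ratio test).  A Levenberg-Marquardt polish on the scaled gradient norm
finishes flat valleys.  Convergence is declared on the physical residual —
net force per free segment, net torque divided by 100 mm — at a default
tolerance of 1e-3 N; non-convergence returns diagnostics, never a silent
pose.  Scenario solves continue from one another: flatfoot warm-starts
from intact through intermediate attenuation factors (0.85, 0.7, 0.6),
reconstructions warm-start from flatfoot with the graft modulus ramped
(0.1, 0.3, 1.0).  Everything is deterministic for fixed inputs.

Nonsmoothness is regularized, not branched: contact activation and every
assembled element's slack point are smoothed over fixed small zones
(0.02 mm penetration, 0.01 mm elongation) by a quadratic ramp with
closed-form energies, keeping the total energy C2.  The public law
functions and standalone elements remain exact; the regularization is a
property of assembled models and is negligible at working loads (force
offsets below ~1 N).

The load-displacement protocol (0 to 600 N in 100-N steps) runs each step
warm-started and measures the vertical drop of the navicular tuberosity
relative to the zero-load solve.  Near zero load several contacts and ties
sit exactly at their activation boundaries (a nonsmooth equilibrium), so
loads below 50 N use a relaxed 0.05 N residual tolerance; all loaded steps
converge at the full 1e-3 N tolerance.  The resulting curve shows a large
first seating step followed by a quasi-linear response whose incremental
compliance wanders within a few percent and drifts slightly upward toward
600 N: in this reduced model the exponential ligaments' material
stiffening is offset by geometric softening of the arch, so the response
is not strictly stiffening beyond the seating step (see Known
limitations).

## Measures

A measurement frame is built from the pose itself (vertical axis from the
tibial shaft, anterior axis from the first metatarsal), making all angles
exactly invariant to rigid transforms of the whole pose.  Lateral Meary:
talar vs first-metatarsal axes in the sagittal projection (positive =
dorsiflexion deformity).  AP Meary: same axes in the transverse projection
(positive = abduction).  Hindfoot valgus: tibial vs calcaneal axes in the
coronal projection (positive = valgus; the calcaneal axis template is
vertical so that foot yaw does not bleed into the coronal measure).  All
deformity angles are differences from the solved intact condition;
correction = flatfoot deformity minus residual deformity.  Contact
statistics are area-weighted over patch points in contact; the reported
"pressure" is the penalty-foundation pressure, an admitted surrogate for
continuum contact stress, and absolute MPa values should not be compared
against deformable-cartilage results.

## Design decisions

* **Muscle default = zero activation.**  The muscle elements (seven
  tendons, routed with via points) are always assembled, but the default
  constant forces are zero.  With the tibia on a vertical rig no tendon
  force is needed for balance, and experiments with constant (open-loop)
  activation tables showed they inject coronal-plane artifacts at mild
  attenuation — the hindfoot-valgus response of the reduced skeleton is a
  sub-degree signal that constant tendon pulls can flip — and at higher
  activation destabilize the strongly attenuated arch outright.  A
  documented relaxed-standing table (`STANDING_MUSCLE_FRACTIONS`, e.g.
  Achilles at 12.5% of load) ships as a sensitivity condition and is
  exercised by the test suite at the half-stiffness flatfoot point.
* **Attenuated deltoid = all four modeled tibial-origin bands**
  (anterior/posterior tibiotalar, tibiocalcaneal, tibionavicular); the
  named "deltoid" is not itemized further in the source material.
* **Segment frame, coordinates, and cartilage thickness** (1 mm per side,
  configurable) are package choices where the source is silent.

## Known limitations

* The navicular load-displacement response stiffens enormously across the
  initial seating step but is only quasi-linear beyond it, with a slight
  compliance rise toward 600 N (geometric softening of the arch offsets
  the ligaments' exponential material stiffening).  The drop is monotone
  in load; the incremental compliance is not strictly decreasing.
* The hindfoot-valgus response at mild attenuation (factors 0.9–0.7) sits
  at the model's coronal noise floor (about ±0.5 deg): its sign wanders
  with sub-newton modeling perturbations, and the attenuation sweep is
  therefore not guaranteed monotone in valgus even though the
  half-stiffness endpoint is robustly positive.  Lateral and AP Meary are
  monotone throughout.
* Under 1 mm landmark jitter, the combined reconstructions (CSILR, CSPLR)
  can lose their stable equilibrium branch on some geometries: the stiff
  tibial/plantar limbs drive the midfoot past the congruence stops and the
  solver reports non-convergence rather than a spurious pose.  The intact
  and flatfoot conditions and the single-limb reconstructions are robust
  in the same envelope.
* Absolute angles, drops and pressures are properties of the synthetic
  template, not of any subject; only directions, orderings and
  monotonicities are asserted.
* No dynamics, no friction, no bone-tunnel mechanics, no tendon wrapping
  over bone surfaces (via-point polylines only), no viscoelasticity or
  rupture.
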