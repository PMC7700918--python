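# Methods

This note records the models, parameters and numerical choices behind
`tangentplan`, and what the synthetic test bed does and does not show.

## The planning problem

Tangential whole-breast hybrid IMRT: two opposed oblique beams share a
nondivergent posterior edge; open conformal segments carry most of the
prescription (5000 cGy/25 or 4240 cGy/16) and small modulated fields
tune the distribution. Plan quality is judged by DVH clinical goals
(coverage PTV D95 > 95% of prescription; lung/heart/contralateral
constraints) and by three published protocol tables (EviQ, RTOG 1005,
London Cancer) at ideal/acceptable tiers.

## Synthetic phantom

Analytic solids on a voxel grid (default 2.5 mm, 96x80x48; the coarse
grid is 5 mm), in an LPS-like frame (x patient-left, y posterior,
z superior):

* thorax: elliptical cylinder (semi-axes 9.8 x 8.5 cm) with a flat
  posterior couch cut;
* breast: a 5 cm sphere centred on the anterior chest surface 30 deg
  lateral of midline; the PTV is the bulge outside a "pectoral" core
  (chest ellipse scaled 0.82) and lateral of a 1.5 cm sternal gap, so a
  field edge pinned on the midline tattoo can clear it;
* lungs: ellipsoids (2.9-3.3 x 4.2-4.4 x 7.5 cm) whose ipsilateral
  anterior face lies close enough to the chest wall that tangents include
  a small sliver, as they do clinically;
* heart: 3.4 cm sphere displaced toward the patient's left regardless of
  laterality; contralateral breast: a 3.2 cm bulge.

Densities are conventional relative electron densities (air 0, lung
0.25, tissue 1.0). Each seed jitters the organ dimensions by up to +-4%,
giving distinct but anatomically similar patients; generation is
bit-deterministic per config. The planning PTV retracts the PTV 5 mm
from the skin (Euclidean distance transform against the External mask).
The tattoo is the most anterior midline skin voxel on the PTV mid-plane.

What the phantom does *not* emulate: real contour irregularity, chest
wall curvature along z, breathing motion, couch/bolus, CT artefacts, and
realistic contralateral scatter. Passing tests show the algorithmic
pipeline behaves as specified on plannable geometry, not that clinical
plan quality statistics would be reproduced on patients.

## Tangent geometry

The posterior field edge is found by scanning directed edge normals in
0.5 deg steps over the full circle about the tattoo. Feasibility demands
every planning-PTV voxel (axial projection) lie on the field side by a
1 cm margin; because a line pinned on the skin cannot clear target
voxels closer than the margin's lever arm, the required margin tapers
linearly from zero within 2 cm of the tattoo to the full value at 6 cm.
Among feasible rotations the one including the least External mid-plane
area wins (ties to the smaller area, i.e. the more sparing rotation).

Border points are the edge line's first/last crossings of the mid-plane
skin (quarter-voxel sampling; fewer than two crossings raises a
degenerate-geometry error). They are reported with the lateral axis
positive toward the ipsilateral side and y positive posterior; in that
frame one arctangent formula pair with a 360-minus switch for left-sided
patients yields the correct IEC gantry angles for both lateralities, and
a post-hoc check asserts the IEC source direction implied by the
reported angle coincides with the geometric medial-entry beam axis.
Angles round half-to-even to whole degrees; the isocenter's displacement
from the tattoo along the tangent rounds half-to-even to whole
centimeters (the cross-line component stays exact, keeping the isocenter
on the nondivergent edge). The wide-field branch (lateral border
separation >= 10 cm) steps 10 cm from the medial border along the border
line. The collimator is fixed at 0 deg with the posterior edge carried
by the jaw. Mixed 6/18 MV beams appear only when the border separation
strictly exceeds 25 cm.

Apertures: per 5 mm leaf row, the anterior tip encloses the BEV
projection of the PTV dilated by 7 mm, extended 2 cm beyond the
projected skin (flash) within the target rows; heart/lung sparing during
aperture creation is carried entirely by the tangent-line optimization
(no per-leaf organ trimming). The modulated beams reuse the open
geometry with flashless apertures.

## Dose engine

A deliberately simple linear model standing in for a commercial
convolution algorithm:

    D(x) = w * F_blur(u(x), v(x)) * exp(-mu * d_rad(x))
             * (1 - exp(-beta * d_rad(x))) * (SAD / r(x))^2

with radiological depth d_rad by ray sampling of the density grid
(2.5 mm steps, rays clipped to the grid bounding box), magnification
onto the isocenter plane, and a Gaussian penumbra (sigma 3 mm) applied
to the fluence as products of normal-CDF differences per pixel — which
makes dose exactly linear in fluence and lets beamlet columns sum to the
open field to machine precision (verified at 1e-6 relative). Defaults:
mu 0.046/0.030 cm^-1 and build-up beta 3.2/1.4 cm^-1 for 6/18 MV,
chosen to track published depth-dose behaviour (80% at 5 mm, ~96% at
10 mm for 6 MV), not commissioned data. The build-up factor matters:
without it the model's maximum sits on the skin, which both misstates
surface dose and breaks the 85%/95% open-weighting interplay; with it,
surface voxels are cold and the 5 mm PTV retraction keeps them out of
the optimization, as intended. Dose is computed only inside the External
contour. Fluence pixels are 5 x 5 mm at isocenter, clipped to the
aperture.

Open weighting: equal medial/lateral weights scaled to a planning-PTV
mean of 0.85 x prescription, rescaled down if the body maximum would
exceed 0.95 x prescription (on the default phantom the cap binds
mildly, landing the mean at ~82.5%); energy copies at one gantry angle
share that angle's weight equally.

## Objectives and optimizer

Normalized one-sided quadratic penalties; DVH objectives re-identify
their violating voxel subset each iteration (for V_D < v%, the hottest
v% are exempt and the remaining lowest-dose violators are pushed down;
coverage objectives symmetrically). The optimizer is projected gradient
descent with Armijo backtracking (c = 1e-4, step halving, doubling on
acceptance), zero initial fluence, non-negativity by projection, an
"iteration" being one accepted step; convergence at relative objective
change below 1e-8. It is deterministic; warm starts carry the fluence
between rounds. The optimization grid is ~5 mm (fine phantoms are
block-averaged 2x); goal evaluation and the final dose use the fine
grid. The shipped objective template weights OAR terms 5x the target
terms so early rounds trade coverage against one organ at a time.

## The goal-driven loop

Linking: same structure, compatible metric family (DVH-volume goals
accept max_dvh then max_dose objectives; coverage goals min_dvh then
min_dose; mean goals only mean objectives), with max-type goals
restricted to objective dose levels at or below the goal and min-type
goals at or above; the closest dose level wins, ties to the DVH-kind
then the earlier row. Goals with no candidate are reported unlinked and
never drive escalation.

Escalation: factor = clamp(1.2 + 1.8 * proximity, 1.2, 3.0), where
proximity = |achieved - limit| / limit on the goal's own scale. Several
failing goals sharing one objective escalate it once per round by the
largest factor. Goal inequalities are strict: achieved == limit fails.

Tightening: an OAR max-type objective whose penalty is exactly zero
(<= 1e-12) on the round's fine-grid dose has its dose level set to 90%
of the achieved statistic (max, mean, or dose-at-volume for DVH kinds).
Statistics below 10 cGy are left alone — tightening toward zero dose
would make the normalized penalty singular and there is nothing left to
spare. Tightening may repeat across rounds and always forces at least
one more round.

Loop control: 100 iterations per round, at most 600 total (6 rounds).
The final status is "all-goals-met" iff the last round's goals all pass,
else "max-iterations-reached" (never an exception on a feasible
geometry).

## Evaluation conventions

Cumulative DVHs by voxel counting at 1 cGy bins; V(d) uses a closed
threshold (>= d); dXX inverts the cumulative curve with linear
interpolation, returning the highest dose still covering XX% on
plateaus. Metrics from hypofractionated plans scale by 5000/prescription
for analysis. Protocol tables ship as a CSV resource encoding the three
guidelines exactly as printed, including the uneven RTOG heart
ideal-vs-acceptable pairing (V20 < 5% ideal vs V25 < 5% acceptable) and
the bare contralateral-breast bound (encoded as a mean-dose limit; the
printed d5 row bounds the near-maximum separately). The 4240 regime is
checked at the parenthesized alternate levels by default; a "scaled"
mode instead applies the primary levels to 5000-scaled metrics, and
reports name the mode. The plan-maximum target constraint (< 110%) is
evaluated over the whole body. Quartile bands use linear-interpolation
(type-7) percentiles.

## Problem sizes and runtimes

Defaults chosen so the whole pipeline is interactive on one CPU: fine
grid 96x80x48 at 2.5 mm (~211k body voxels), optimization grid 5 mm
(~26k body voxels, ~800 beamlets, ~2-3 M sparse entries). A complete
automated plan takes ~10-15 s; the acceptance script about half a
minute; multi-phantom sweeps use natively 5 mm phantoms (48x44x24).

## Known limitations

* The dose model has no scatter kernel, MLC transmission or tongue-and-
  groove; contralateral structures receive essentially zero dose, so
  contralateral goals are trivially met here while they are not on
  patients.
* Fluence is not sequenced into deliverable DMLC segments; MU and
  delivery QA are out of scope.
* On natively coarse (5 mm) phantoms the coverage goal may be
  unreachable because build-up-region voxels dominate the retracted PTV
  shell; the loop then reports "max-iterations-reached" honestly.
* The phantom's left/right cases are not exact mirrors (the heart stays
  on the left), which is intentional.
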