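# tangentplan

Automated, single-click treatment planning for tangential whole-breast
radiotherapy with the hybrid IMRT technique, implemented as a tested
Python pipeline that runs end-to-end on synthetic voxel phantoms.

Whole-breast radiotherapy is planned with two opposed oblique ("tangent")
photon beams grazing the chest wall. In the hybrid technique, open
conformal tangents deliver most of the prescription and low-weight
modulated (DMLC) fields of identical geometry fine-tune coverage and
homogeneity. Producing such a plan manually is an iterative dialogue
between a dosimetrist and the optimizer: run some iterations, check the
plan against clinical DVH goals, raise the weights of objectives tied to
failing goals, tighten objectives that turned out trivially easy, repeat.
`tangentplan` automates that entire dialogue — beam geometry included —
for medical-physics researchers who want to study goal-driven automated
planning without a commercial treatment planning system.

## What it implements

* **Synthetic phantoms** (`tangentplan.phantom`) — seeded, deterministic
  thorax/breast voxel models with every contour the planner needs (PTV,
  skin-retracted planning PTV, lungs, heart, contralateral breast,
  External, midline tattoo), saved/loaded as HDF5.
* **Tangent geometry** (`tangentplan.geometry`) — the posterior field
  edge is optimized by rotating a line about the midline tattoo until the
  PTV (plus margin) is covered with minimal included body area. From its
  skin intersections — the medial and posterior **border points**
  (x_m, y_m), (x_p, y_p) — the medial gantry angle follows as

      θ_m = atan[(x_m − x_p)/(y_m − y_p)]        (right-sided)
      θ_m = 360° − atan[(x_m − x_p)/(y_m − y_p)] (left-sided)

  rounded to the nearest degree, with the lateral beam exactly opposed
  (closed-jaw nondivergent posterior edge, posterior jaw = 0.0 cm). The
  isocenter is the border midpoint (or a 10 cm step from the medial
  border for wide fields), snapped to whole-centimeter shifts from the
  tattoo along the tangent. Border separations over 25 cm duplicate the
  open pair, split equally between 6 and 18 MV. Conformal MLC apertures
  enclose the PTV projection with 2 cm anterior flash.
* **Dose engine** (`tangentplan.dose`) — a simplified, strictly linear
  photon model (divergent source at SAD 100 cm, exponential attenuation
  with radiological depth, exponential build-up, inverse square, Gaussian
  penumbra) providing per-beam dose grids and sparse beamlet
  dose-influence matrices whose columns sum exactly to the open field.
  Open segments are weighted to deliver **85%** of prescription to the
  planning PTV on average, capped so the open-field maximum stays below
  **95%**.
* **Objectives and fluence optimization** (`tangentplan.objectives`) —
  normalized one-sided quadratic penalties (min/max/uniform dose, DVH,
  mean) and deterministic projected-gradient descent over non-negative
  fluence, with the open dose as fixed background.
* **The iterative loop** (`tangentplan.autoloop`) — clinical goals and
  objectives load from CSV; each goal links to the objective of matching
  structure/metric family with the closest dose level (minimum-dose goals
  only link upward). Per round: 100 optimizer iterations, a full
  fine-grid dose calculation, goal evaluation, weight escalation by a
  factor in [1.2, 3] proportional to the relative violation, and
  tightening of any organ-at-risk objective with value exactly zero to
  90% of its achieved dose. The loop stops when all goals pass with
  nothing tightened, or at 600 total iterations.
* **Evaluation** (`tangentplan.evalx`) — cumulative DVHs, dXX / Vd /
  mean / max metrics, scaling of hypofractionated (4240 cGy/16) results
  to the 5000 cGy analysis scale, compliance scoring against the EviQ,
  RTOG 1005 and London Cancer constraint tables
  (ideal / acceptable / fail), and median-IQR cohort DVH bands.

## Worked example

```python
from tangentplan import (PhantomConfig, generate_phantom, run_autoplan,
                         default_goals_path, default_objectives_path)

patient = generate_phantom(PhantomConfig(seed=1, laterality="left"))
plan, report, trace = run_autoplan(
    patient, default_goals_path(), default_objectives_path(),
    prescription=5000.0, fractions=25)
```

Running `python examples/04_autoplan.py` (which does exactly this)
prints:

```
status: all-goals-met after 2 rounds (200 optimizer iterations)
  round 1: objective 0.9198 -> 0.005651, PTV d95 4882 cGy, 0 escalations, 1 tightenings
  round 2: objective 0.02784 -> 0.005814, PTV d95 4891 cGy, 0 escalations, 0 tightenings
clinical goals:
  PASS  PTV_planning D95>4750cGy                 achieved 4891.3
  PASS  PTV_planning Max<5500cGy                 achieved 5385.3
  PASS  Ipsilateral Lung V2000cGy<15%            achieved 2.9
  ...
protocol verdicts: {'EviQ': 'ideal', 'RTOG1005': 'ideal', 'LondonCancer': 'ideal'}
```

Round 1 optimizes the modulated fluence on top of the ~82.5%-weighted
open fields and already meets every goal, but the ipsilateral-lung
objective came out trivially satisfied, so its dose level is tightened to
90% of the achieved dose and a second round squeezes the lung further
before the plan is accepted. The final plan covers 95% of the planning
PTV with 4891 cGy (97.8% of prescription) and is *ideal* under all three
protocol tables.

The same pipeline is available from the shell:

```bash
tangentplan auto --seed 1 --out report.json --dose-out dose.h5
tangentplan phantom --seed 2 --out p.h5
tangentplan plan --phantom p.h5 --out report.json
tangentplan evaluate --phantom p.h5 --dose dose.h5 --protocol RTOG1005
```

More narrative scripts live in `examples/`.

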