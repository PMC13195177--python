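# ofvplan

Objective-function-value (OFV)–guided automated VMAT plan optimization on
synthetic thoracic phantoms.

## The problem

Inverse planning for whole-breast VMAT is usually stopped as soon as the
institutional dose constraints are met, which leaves organ-at-risk (OAR)
sparing on the table and makes plan quality depend on the individual
planner.  An alternative is to let the optimizer itself report how hard
each constraint is being fought — the per-objective **objective function
value (OFV)** — and to keep tightening each organ's **MaxEUD** limit (an
upper bound on its generalized equivalent uniform dose) until the OFV
signals that further sparing would start to cost target coverage.  At that
point the plan has reached *saturation*: the physical limit of sparing for
that anatomy.

`ofvplan` implements this controller end to end as a self-contained
research tool for medical-physics algorithm work: a seeded 2-D thoracic
phantom generator (PTV = ipsilateral breast, heart, both lungs,
contralateral breast), a pencil-beam influence-matrix surrogate for the
dose engine, a bound-constrained fluence optimizer, the phased OFV-feedback
outer loop, the sensitivity-analysis procedure that calibrates the
controller's tuning points, and standard plan-quality metrics (DVH,
V_xGy / D_x%, Paddick CI, homogeneity index, clinical-goal tables).
No patient data, TPS, or DICOM input is required; everything is generated
from a seed.

## The control law

Each objective term reports a weighted, dimensionless OFV.  With the target
prescribed D_p = 50 Gy (2 Gy fractions), PTV weight 3000 and a uniform OAR
weight of 10:

* PTV: `w · mean(((d_i − D_p)/D_p)²)`
* OAR MaxEUD: `w · (max(0, gEUD_a(d) − EUD₀)/EUD₀)²`, with
  `gEUD_a = ((1/N)Σ d_iᵃ)^{1/a}` (a = 1, i.e. mean dose, for the parallel
  organs handled here)

After every inner optimization (one 40-iteration fluence solve per loop)
the controller reads each OAR's OFV and rescales its MaxEUD limit:

```
s_OFV = 0.44 · OFV + 0.8     (class 1: contralateral lung and breast)
s_OFV = 0.089 · OFV + 0.8    (class 2: ipsilateral lung and heart)
MaxEUD_{n+1} = clamp(s_OFV · MaxEUD_n)
```

Each law is a linear feedback with fixed point `(1 − 0.8)/m`: **0.45** for
class 1 and **2.25** for class 2.  Below the fixed point the limit
tightens (s < 1); above it the limit relaxes, protecting target coverage.
Phase 1 starts every MaxEUD at D_p; Phase 2 jumps to 50 % (class 1) or
20 % (class 2) of the Phase-1 mean organ dose; Phase 3 iterates the law
until s ≈ 1 on both class-2 organs for two consecutive loops.  If PTV
V95 % has slipped, a repair step adds a minimum-dose objective on the
Boolean intersection of the PTV with the sub-95 %-isodose region and
re-optimizes with frozen limits.

The tuning points themselves come from a sensitivity analysis
(`ofvplan.sensitivity`): drive one organ's limit down a geometric schedule
(50 %, 25 %, then ×0.8 per step), trace six plan metrics, smooth with a
three-point moving average, take finite differences, gate them with
clinical criticality masks, and sum the gated |derivatives| into a score
S(j); the argmax marks the OFV beyond which sparing trades against
coverage.

## Worked example

```
$ ofvplan plan run --out plan_out/
ofvplan run (seed 7, left-sided, D_p = 50.0 Gy)
outer loops: 9 (saturated: True, loop 9)
PTV V95%: 93.57 %   CI: 0.895   HI: 1.119
         heart: mean   2.34 Gy
     lung_ipsi: mean   7.18 Gy
   lung_contra: mean   0.91 Gy
 breast_contra: mean   1.57 Gy
```

The controller saturated at loop 9: both class-2 OFVs sit near the 2.25
fixed point (heart 2.29, ipsilateral lung 2.46 in `trajectory.csv`), and
the mean doses have fallen from their unconstrained Phase-1 values
(heart 15.5 → 2.34 Gy, ipsilateral lung 26.7 → 7.18 Gy) to the phantom's
sparing floor.  All six institutional clinical goals in `report.json` pass
(e.g. heart mean ≤ 2.5 Gy, ipsilateral lung V20 < 20 %).  The run
directory also contains the phantom container, per-structure DVHs, and the
per-loop trajectory behind these numbers.

Library use mirrors the CLI:

```python
from ofvplan import (PhantomConfig, generate_phantom, build_beamset,
                     compute_influence, ControllerConfig, run_controller)

phantom = generate_phantom(PhantomConfig(), seed=7)
beamset = build_beamset(phantom)                  # left arc 180°–288°
plan, log = run_controller(phantom, beamset, ControllerConfig())
print(log.saturated, plan.report.mean_dose["heart"])
```

## Scope notes

The dose engine is a 2-D pencil-beam surrogate (exponential depth
attenuation, double-Gaussian lateral profile), not a clinical dose
calculation: control-law behavior is comparable to clinical experience,
absolute dosimetry is not.  MLC sequencing, monitor units, DICOM-RT
export, and 3-D dose calculation are out of scope.  See `docs/methods.md`
for the model, parameter choices, and known limitations.
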