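# Methods

This note documents the models behind `anatrobust`, the defaults and why,
and what the synthetic setting does and does not show about real patients.

## Synthetic longitudinal phantoms (`phantom_cohort`)

**Anatomy.** Patients are idealized nasopharynx anatomies on a regular voxel
grid (default 64 x 64 x 48 at 3 mm isotropic) of relative stopping power
(RSP): air 0.001, soft tissue 1.0, vertebral bone 1.4.  Structures are
analytic solids: a central high-risk CTV (primary sphere, r = 20 mm, plus two
lateral nodal ellipsoids), a bilateral elective low-risk collar inferior to
it, parotids lateral to the nodal levels with a ~6 mm gap to the target,
submandibular glands, oral cavity, three pharyngeal-constrictor segments
(deliberately overlapping the CTVs, as in real patients), brainstem, spinal
cord inside a bone column, optic chiasm and thyroid.  All masks are evaluated
from implicit functions, so deformed masks are exact to sub-voxel accuracy.

**Progression.**  Interfractional change is a single smooth family of
week-to-planning pull-back fields evaluated at fractions 5, 10, ..., 30
(weeks 1-6), composed of per-organ contraction/translation fields with
compact support, a surface-weighted neck-contraction field and an optional
random smooth "small nonrigid variation" (sNRV) field.  Inside an organ's
plateau the map is an exact similarity transform, so a loss fraction `f`
yields a warped volume of `1 - f` by construction; the radial term saturates
at the plateau edge to limit cross-talk between neighbouring organs.
Composition of overlapping fields still perturbs neighbouring volumes by a
few per cent — per-organ calibration is exact in isolation only.

Defaults are the emulated cohort's course statistics: volume-loss rates of
1.5 / 2.3 / 0.3 % per treatment day for the primary, nodal and elective CTVs,
28.6 +- 14.6 % total parotid loss with a 2.3 mm medial shift, 26.6 +- 17.1 %
submandibular and 12.3 +- 11.3 % thyroid loss, CTV displacements between
roughly 2.5 and 3.7 mm (population truncation bounds follow that range), a
3 mm neck contraction and 1 mm RMS sNRV.  Progression is linear in treatment
days; sNRV is drawn independently per week (trendless by definition), while
all progressive terms are one parameterized family.  Ground-truth forward
fields (planning -> week) are obtained by damped fixed-point inversion of the
analytic pull-back, coarse-to-fine; the 99th-percentile composition residual
is well below 0.25 voxel.

Cohorts draw per-patient parameters from truncated normal distributions with
deterministic child seeds (`SeedSequence([master, index])`), so a fixed master
seed reproduces the cohort bit for bit.

## Average deformation model (`anatomy_model`)

The model is the voxelwise arithmetic mean of the training patients' weekly
forward fields.  Synthetic patients share one template frame, so inter-patient
correspondence is the identity — a stated simplification standing in for
registration-based correspondence on real cohorts.  Prediction warps the
planning image (trilinear) and propagates contours (nearest-neighbour)
through the numerically inverted mean field; the high-risk CTV is copied from
planning unchanged, mirroring the clinical contour rule that never relaxes the
boost target.  Validation is leave-one-out: symmetric mean surface distance
(6-connectivity boundary voxels, exact Euclidean distance transform) between
predicted and true weekly contours, against the planning-contour (no-model)
baseline.

## Dose engine (`dose_engine`)

Each spot is a Bortfeld-parameterized Bragg curve in water-equivalent depth
multiplied by a lateral 2-D Gaussian in the beam's-eye view.  Choices:

* **Depth dose** — the analytic piecewise Bortfeld forms (power-law plateau,
  parabolic-cylinder-function peak) with the straggling width floored at
  3.5 mm (5 mm in the study configuration) to emulate the energy-spread /
  ridge-filter smoothing a clinical beamline provides; the curve is tabulated
  at 0.2 mm and the nominal range is calibrated so the distal-80 % depth
  equals the requested R80.
* **Lateral model** — single Gaussian, no nuclear halo; sigma grows linearly
  with depth and is evaluated at each spot's Bragg depth (sigma0 + k R80,
  k = 0.015/mm), which keeps the beam dose separable per energy layer.
* **Parallel beams** — infinite source distance, six axial gantry angles
  (45, 315, 90, 270, 160, 200 degrees).  WEPL is computed by rotating the RSP
  grid so the beam runs along an array axis, cumulative-summing, and rotating
  back; accurate within the inscribed cylinder of the grid, which contains
  the whole body of the phantom.
* **Scenarios** — under the parallel-beam model a rigid patient shift leaves
  WEPL at a tissue point unchanged (the beam enters the shifted surface at
  the shifted position) and acts as a lateral offset of the spot lattice per
  beam; range error divides the water-equivalent depth fed to the Bragg
  curve.  Both are exact analytic transformations, so scenario doses need no
  resampling of the anatomy.
* **Fast path** — for a fixed plan, each beam's dose is the separable table
  `T(WEPL, u, v) = sum_layers B_layer(WEPL/rho) L_layer(u, v)`, built once
  and interpolated trilinearly; it is anatomy-independent and validated
  against exact superposition to ~1 % in the tests.

The spot lattice covers the union of both CTVs with a lateral margin of the
setup magnitude plus a penumbra allowance, with energy layers spanning each
lateral site's target WEPL chord plus a 4 mm range margin.  The library
default lattice pitch is 5 mm; the study configuration uses 13 mm lateral /
10 mm layer spacing with sigma0 = 5 mm, a resolution chosen to keep the full
three-strategy, ten-patient study in the tens of minutes on one CPU while
preserving dose-ripple below the few-per-cent level.

## Minimax optimization (`robust_opt`)

The optimizer solves `min_{w >= 0} max_s f_s(w) + lambda f_nom(w)` where `s`
runs over the strategy's error scenarios (per anatomy, the 14-direction setup
set crossed with +-3 % range: 28 per anatomy, 112 for aRO1mm) and `f` is a
composite objective: one-sided quadratic penalties (Gy^2, averaged per
structure) for CTV minimum/maximum dose and serial-organ ceilings, and linear
mean-dose terms for the parallel organs that only the nominal scenario
evaluates (`lambda` = 1).  Mean-dose terms are evaluated on the organ volume
outside the targets, so constrictor-CTV overlap is owned by the coverage
terms.  Default levels and weights are derived from the clinical goal sheet
(coverage terms at the prescriptions with dominant weight, serial ceilings
below their hard limits, a normal-tissue conformity shell whose guard band
scales with the setup magnitude); they are configuration, not claims — the
reference planning system's internal objectives are not public.

Numerically, all per-spot scenario doses are precomputed at the objective's
(surface-weighted, subsampled) structure voxels into one stacked float32
influence matrix; the nonsmooth max is smoothed by log-sum-exp with two
annealed temperatures (3 % and 0.5 % of the initial objective scale), each
stage solved by bound-constrained L-BFGS-B, warm-started, while the best
iterate by the *true* worst case is tracked — the reported trace is therefore
nonincreasing and the final worst case can never exceed the initial one.
The optimizer contains no randomness; initialization is uniform weights
scaled to the prescription.

## Course simulation and accumulation (`accumulate`)

Each week's verification anatomy is first rigidly aligned to planning
(sub-voxel cross-correlation; plain normalization, because spectrum-whitening
phase correlation is unreliable on smooth synthetic images), then dosed under
the 28 residual scenarios (14 x 1 mm crossed with +-3 %).  The nominal dose
joins the worst-case stack so voxmin <= nominal <= voxmax holds voxelwise.
Doses are pulled into the planning frame through the ground-truth forward
fields (`warped(x) = dose_week(x + u(x))`, trilinear) — an exact stand-in for
deformable registration — and summed with weights 5,5,5,5,5,10 of 35
fractions (weeks map to fraction blocks; the last block reuses the week-6
anatomy).  Accumulating voxmin with voxmin and voxmax with voxmax is a
conservative convention: worst cases need not co-occur across weeks.  Dose
(not energy) is interpolated, acceptable at phantom scale where density is
near-uniform.  The pipeline evaluates the scenario sweep only at the
forward-warped structure voxels, which is exactly what planning-frame DVH
metrics require; the full-grid path exists and the two agree to
interpolation tolerance.

## Evaluation (`metrics`)

V94 counts structure voxels at or above 94 % of the structure's prescription;
D2 % and D0.03 cc interpolate linearly on the sorted cumulative-volume curve
(0.03 cc is ~1.1 voxel at 3 mm).  The gamma index is global (reference-max
normalization), evaluated at voxel resolution with the offset search capped
at three DTA widths.  The Wilcoxon signed-rank test drops zero differences,
uses average ranks, and enumerates the exact null distribution by dynamic
programming for up to 25 pairs (normal approximation beyond).  NTCP uses the
accumulated nominal mean doses in physical Gy without fractionation
correction; the ipsilateral parotid is the higher-dose side; the dysphagia
site term is active (nasopharynx is a pharyngeal site).  Clinical goals:
V94(voxmin) > 98 % for both CTVs, CTV D2(voxmax) < 77 Gy, brainstem
D0.03 cc < 68 Gy (voxmax) / 63.1 Gy (nominal), cord 58.5 / 55 Gy, optics
64 / 59.5 Gy; replanning is flagged when accumulated CTV V94(voxmin) drops
below 94 %.

## Study design (`pipeline`)

Twenty template-cohort patients, the first ten used for validation; for each,
the average model is trained on the other nineteen (leave-one-out — the
validation patient's data never enter its own model, which a test audits
explicitly).  Because every synthetic patient shares the template planning
anatomy, the two conventional strategies see identical planning inputs and
are optimized once per study; the anatomy-aware plan is re-optimized per
validation patient with its fold's model.  All three plans are evaluated on
the same simulated course.

## What the phantom study shows — and what it does not

The phantom reproduces the comparison logic: 3 mm conventional robustness
keeps every patient's accumulated V94(voxmin) above 98 %; dropping to 1 mm
degrades coverage on high-progression patients; adding predicted anatomies
at 1 mm keeps every plan within the planning goal sheet and the elective
volume covered through the course, while the parallel-organ mean doses
and both NTCPs sit far below the 3 mm plans (and close to cRO1mm's, as the
nonsignificant aRO1mm-vs-cRO1mm differences in the source cohort would
suggest).  Two caveats.  First, the phantom's deformation is
shrinkage-dominated: tissue tends to move *into* the dose bath, so the
anatomy-aware scenarios buy robust-planning-goal feasibility and OAR sparing
rather than the rescue of large accumulated coverage losses; real cohorts
with outline-driven range changes can show larger aRO-vs-cRO1 coverage
separation.  Second, effect magnitudes (NTCP reductions of several per cent,
parotid mean-dose reductions of several Gy) depend on the idealized geometry
and the equal optimization budget per strategy; only their directions are
asserted.  Degenerate inputs are handled explicitly: zero progression gives
bit-identical weekly anatomies and identity fields; a zero-residual course
reduces the scenario stack to the nominal dose; an empty scenario set reduces
the minimax to plain weighted least squares.
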