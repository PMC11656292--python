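"""Treatment-course simulation and deformable dose accumulation.

Each treatment week is delivered on that week's verification anatomy under
residual uncertainty (the 14-direction setup set at 1 mm crossed with +-3%
range scaling, 28 scenarios).  Per week the nominal, voxmin and voxmax doses
are computed, warped into the planning frame through the ground-truth
forward displacement field (``warped(x) = dose_week(x + u(x))``), and summed
with the week's share of the 35 fractions.  Worst-case channels accumulate
with worst-case channels (voxmin with voxmin, voxmax with voxmax) — a
conservative convention, since worst cases need not co-occur across weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from .dose_engine import DoseCalculator, EngineConfig, PlanTables, Scenario, SpotPlan
from .grids import DisplacementField, DoseGrid, VoxelGrid, warp_scalar
from .phantom_cohort import WEEKS, PatientTimeline
from .scenario_eval import WorstCaseDose, enumerate_eval_scenarios


@dataclass(frozen=True)
class CourseSpec:
    """Fractionation and residual-uncertainty settings of the course."""

    fractions_total: int = 35
    #: fractions delivered on each weekly anatomy (weeks 1..6); fractions
    #: 31-35 reuse the week-6 anatomy
    week_fraction_weights: tuple[int, ...] = (5, 5, 5, 5, 5, 10)
    residual_setup_mm: float = 1.0
    range_frac: float = 0.03

    def __post_init__(self):
        if sum(self.week_fraction_weights) != self.fractions_total:
            raise ValueError("week fraction weights must sum to the total")
        if len(self.week_fraction_weights) != len(WEEKS):
            raise ValueError(f"need one weight per week ({len(WEEKS)})")


@dataclass
class AccumulatedDose:
    nominal: DoseGrid
    voxmin: DoseGrid
    voxmax: DoseGrid
    per_week: list[WorstCaseDose] = field(default_factory=list)


def align_vct(vct: VoxelGrid, planning: VoxelGrid) -> np.ndarray:
    """Translation (mm) that aligns the vCT to the planning grid.

    Sub-voxel rigid registration by phase cross-correlation; adding the
    returned vector to vCT coordinates maps them onto planning coordinates
    (for a vCT that is the planning image shifted by +s, the result is -s);
    the residual patient displacement in the aligned frame is its negative.
    Falls back to the identity with a warning-free zero vector if the images
    carry no overlapping content.
    """
    if vct.grid.shape != planning.grid.shape:
        raise ValueError("vCT and planning grids must share one shape")
    if not (np.any(vct.values > 0) and np.any(planning.values > 0)):
        return np.zeros(3)
    # cross-correlation normalization: the spectrum-whitening "phase" mode
    # is unreliable on smooth low-texture images, so plain correlation is used
    shift_vox, _, _ = phase_cross_correlation(
        planning.values, vct.values, upsample_factor=10, normalization=None)
    return np.asarray(shift_vox) * planning.grid.spacing_arr


def warp_to_planning(dose: DoseGrid, dvf: DisplacementField) -> DoseGrid:
    """Pull a weekly-frame dose into the planning frame via the forward DVF."""
    return DoseGrid(warp_scalar(dose.values, dvf, order=1, cval=0.0),
                    dvf.grid)


def residual_scenarios(course: CourseSpec, anatomy_id: str = "vct"
                       ) -> list[Scenario]:
    """The per-week residual error scenarios (28, or none if error-free)."""
    if course.residual_setup_mm <= 0 and course.range_frac <= 0:
        return []
    if course.residual_setup_mm <= 0:
        return [Scenario(anatomy_id, (0.0, 0.0, 0.0), 1.0 + s * course.range_frac)
                for s in (-1, +1)]
    return enumerate_eval_scenarios(anatomy_id, course.residual_setup_mm,
                                    course.range_frac).scenarios


def weekly_worst_case(calc: DoseCalculator, plan: SpotPlan,
                      course: CourseSpec,
                      tables: PlanTables | None = None,
                      base_shift: np.ndarray | None = None
                      ) -> WorstCaseDose:
    """Nominal plus voxmin/voxmax dose over the 28 residual scenarios.

    ``base_shift`` (mm) is added to every scenario shift; it carries the
    rigid-alignment correction of the vCT.  When plan tables are supplied the
    fast tabulated path is used, otherwise exact superposition.
    """
    base = np.zeros(3) if base_shift is None else np.asarray(base_shift)
    scens = residual_scenarios(course)

    def dose_of(scenario: Scenario) -> DoseGrid:
        sc = Scenario(scenario.anatomy_id,
                      tuple(scenario.shift_arr + base), scenario.range_scale)
        if tables is not None:
            g = calc.anatomy.grid
            pts = np.stack([c.ravel() for c in g.coordinate_grids()], axis=1)
            vals = calc.table_dose_at_points(tables, sc, pts)
            return DoseGrid(vals.reshape(g.shape), g)
        return calc.plan_dose(plan, sc)

    nominal = dose_of(Scenario("vct"))
    if not scens:
        return WorstCaseDose(nominal, nominal, nominal)
    # the nominal dose joins the stack so voxmin <= nominal <= voxmax holds
    stack = np.stack([dose_of(sc).values for sc in scens]
                     + [nominal.values])
    g = calc.anatomy.grid
    return WorstCaseDose(DoseGrid(stack.min(axis=0), g),
                         DoseGrid(stack.max(axis=0), g), nominal)


def accumulate_course(plan: SpotPlan, patient: PatientTimeline,
                      course: CourseSpec = CourseSpec(),
                      engine_cfg: EngineConfig | None = None,
                      use_tables: bool = True,
                      align: bool = True) -> AccumulatedDose:
    """Simulate the full course on the weekly anatomies and accumulate.

    Returns planning-frame accumulated nominal/voxmin/voxmax dose grids (the
    per-week worst-case doses are retained in ``per_week``).  Ground-truth
    forward DVFs replace deformable registration, so accumulation is exact
    up to interpolation.
    """
    g = patient.grid
    engine_cfg = engine_cfg or EngineConfig()
    tables = None
    if use_tables:
        tables = PlanTables(plan, engine_cfg,
                            (1.0 - course.range_frac, 1.0,
                             1.0 + course.range_frac))
    acc = {ch: np.zeros(g.shape) for ch in ("nominal", "voxmin", "voxmax")}
    per_week = []
    for w in WEEKS:
        weight = course.week_fraction_weights[w - 1] / course.fractions_total
        vct, _ = patient.weekly[w - 1]
        calc = DoseCalculator(vct, engine_cfg)
        base = -align_vct(vct, patient.planning) if align else np.zeros(3)
        wc = weekly_worst_case(calc, plan, course, tables=tables,
                               base_shift=base)
        per_week.append(wc)
        dvf = patient.true_dvfs[w - 1]
        for ch, dose in (("nominal", wc.nominal), ("voxmin", wc.voxmin),
                         ("voxmax", wc.voxmax)):
            acc[ch] += weight * warp_to_planning(dose, dvf).values
    return AccumulatedDose(
        nominal=DoseGrid(acc["nominal"], g),
        voxmin=DoseGrid(acc["voxmin"], g),
        voxmax=DoseGrid(acc["voxmax"], g),
        per_week=per_week,
    )


# --------------------------------------------------------------------------
# fast point-sampled accumulation (study pipeline)
# --------------------------------------------------------------------------

def accumulate_course_at_points(plan: SpotPlan, patient: PatientTimeline,
                                points_mm: np.ndarray,
                                course: CourseSpec = CourseSpec(),
                                engine_cfg: EngineConfig | None = None,
                                align: bool = True,
                                week_calcs: list[DoseCalculator] | None = None
                                ) -> dict[str, np.ndarray]:
    """Accumulated nominal/voxmin/voxmax at selected planning-frame points.

    Equivalent to :func:`accumulate_course` followed by sampling, but the
    scenario sweep is evaluated only at the forward-warped positions
    ``x + u_w(x)`` of the requested points, which is what DVH metrics on
    planning structures require.
    """
    engine_cfg = engine_cfg or EngineConfig()
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    tables = PlanTables(plan, engine_cfg,
                        (1.0 - course.range_frac, 1.0,
                         1.0 + course.range_frac))
    out = {ch: np.zeros(points_mm.shape[0])
           for ch in ("nominal", "voxmin", "voxmax")}
    scens = residual_scenarios(course)
    for w in WEEKS:
        weight = course.week_fraction_weights[w - 1] / course.fractions_total
        vct, _ = patient.weekly[w - 1]
        calc = (week_calcs[w - 1] if week_calcs is not None
                else DoseCalculator(vct, engine_cfg))
        base = -align_vct(vct, patient.planning) if align else np.zeros(3)
        u = patient.true_dvfs[w - 1]
        warped_pts = points_mm + u.sample(points_mm)
        nom = calc.table_dose_at_points(
            tables, Scenario("vct", tuple(base)), warped_pts)
        if scens:
            stack = np.empty((len(scens) + 1, points_mm.shape[0]))
            for i, sc in enumerate(scens):
                eff = Scenario(sc.anatomy_id, tuple(sc.shift_arr + base),
                               sc.range_scale)
                stack[i] = calc.table_dose_at_points(tables, eff, warped_pts)
            stack[-1] = nom  # keep voxmin <= nominal <= voxmax voxelwise
            vmin, vmax = stack.min(axis=0), stack.max(axis=0)
        else:
            vmin = vmax = nom
        out["nominal"] += weight * nom
        out["voxmin"] += weight * vmin
        out["voxmax"] += weight * vmax
    return out
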