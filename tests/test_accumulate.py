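import numpy as np
import pytest
from scipy import ndimage

from anatrobust.accumulate import (
    CourseSpec,
    accumulate_course,
    accumulate_course_at_points,
    align_vct,
    residual_scenarios,
    warp_to_planning,
    weekly_worst_case,
)
from anatrobust.dose_engine import DoseCalculator
from anatrobust.grids import (
    DisplacementField,
    DoseGrid,
    GridSpec,
    VoxelGrid,
)

NO_ERROR_COURSE = CourseSpec(residual_setup_mm=0.0, range_frac=0.0)


# -- course spec -----------------------------------------------------------

def test_course_spec_validation():
    with pytest.raises(ValueError):
        CourseSpec(week_fraction_weights=(5, 5, 5, 5, 5, 5))
    assert sum(CourseSpec().week_fraction_weights) == 35


def test_residual_scenarios_count():
    assert len(residual_scenarios(CourseSpec())) == 28
    assert residual_scenarios(NO_ERROR_COURSE) == []


# -- rigid alignment -------------------------------------------------------

def test_align_self_is_identity():
    g = _textured_grid()
    assert np.allclose(align_vct(g, g), 0.0, atol=0.1)


def _textured_grid():
    g = GridSpec((32, 32, 24), (3.0, 3.0, 3.0))
    rng = np.random.default_rng(0)
    vals = ndimage.gaussian_filter(rng.random(g.shape), 2.0)
    return VoxelGrid(vals, g)


def test_align_recovers_known_offset():
    planning = _textured_grid()
    shifted = VoxelGrid(ndimage.shift(planning.values, (1.0, 0, 0),
                                      order=1, mode="nearest"),
                        planning.grid)
    # vct = planning shifted by +3 mm in x  ->  recovered about -3 mm
    t = align_vct(shifted, planning)
    assert t[0] == pytest.approx(-3.0, abs=1.5)  # half a voxel
    assert abs(t[1]) < 1.5 and abs(t[2]) < 1.5


def test_align_inverse_consistent():
    planning = _textured_grid()
    shifted = VoxelGrid(ndimage.shift(planning.values, (0, 1.0, 0),
                                      order=1, mode="nearest"),
                        planning.grid)
    ab = align_vct(shifted, planning)
    ba = align_vct(planning, shifted)
    assert np.allclose(ab, -ba, atol=1.0)


# -- warping ---------------------------------------------------------------

def test_warp_identity_field(water_box):
    g = water_box.grid
    rng = np.random.default_rng(1)
    dose = DoseGrid(rng.random(g.shape), g)
    out = warp_to_planning(dose, DisplacementField.zeros(g))
    assert np.allclose(out.values, dose.values)


def test_warp_constant_dose_invariant_in_interior():
    g = GridSpec((20, 20, 20), (2.0, 2.0, 2.0))
    dose = DoseGrid(np.full(g.shape, 5.0), g)
    vec = np.zeros((3,) + g.shape)
    vec[0] = 1.3  # smooth interior displacement
    out = warp_to_planning(dose, DisplacementField(vec, g))
    assert np.allclose(out.values[2:-2, 2:-2, 2:-2], 5.0)


def test_warp_translation_matches_closed_form():
    """Pure translation field on an analytic Gaussian dose equals the
    shifted closed-form evaluation within interpolation tolerance."""
    g = GridSpec((24, 24, 24), (2.0, 2.0, 2.0))
    cx, cy, cz = g.coordinate_grids()
    c = g.origin_arr + g.extent_mm / 2.0

    def gauss(x, y, z):
        return 10.0 * np.exp(-((x - c[0]) ** 2 + (y - c[1]) ** 2
                               + (z - c[2]) ** 2) / (2 * 8.0 ** 2))

    dose = DoseGrid(gauss(cx, cy, cz), g)
    t = np.array([3.0, -2.0, 1.0])
    vec = np.broadcast_to(t[:, None, None, None], (3,) + g.shape).copy()
    out = warp_to_planning(dose, DisplacementField(vec, g))
    expected = gauss(cx + t[0], cy + t[1], cz + t[2])
    interior = (slice(3, -3),) * 3
    assert np.allclose(out.values[interior], expected[interior], atol=0.3)  # trilinear on a 2 mm lattice


# -- weekly worst case and accumulation ------------------------------------

@pytest.fixture()
def small_plan(small_static_patient):
    from anatrobust.dose_engine import make_spot_lattice
    p = small_static_patient
    targets = (p.planning_structures["ctv_high"]
               | p.planning_structures["ctv_low"])
    plan = make_spot_lattice(p.planning, targets, lateral_spacing_mm=14.0,
                             layer_spacing_mm=12.0, sigma0_mm=6.0)
    # scale uniform weights to prescription-like dose in the boost volume
    from anatrobust.dose_engine import NOMINAL
    calc = DoseCalculator(p.planning)
    pts = p.grid.index_to_world(
        np.argwhere(p.planning_structures["ctv_high"]))[::4]
    d = calc.dose_at_points(plan, NOMINAL, pts)
    return plan.with_weights(plan.weights * 70.0 / d.mean())


@pytest.fixture()
def static_weekly_wc(small_static_patient, small_plan):
    calc = DoseCalculator(small_static_patient.planning)
    course = CourseSpec()
    tables = calc.make_tables(small_plan, (1.0 - course.range_frac, 1.0,
                                           1.0 + course.range_frac))
    return weekly_worst_case(calc, small_plan, course, tables=tables)


def test_weekly_worst_case_produces_28_scenarios_and_bounds(static_weekly_wc):
    assert len(residual_scenarios(CourseSpec())) == 28
    wc = static_weekly_wc
    assert (wc.voxmin.values <= wc.nominal.values + 1e-9).all()
    assert (wc.nominal.values <= wc.voxmax.values + 1e-9).all()


def test_robust_core_voxmin_close_to_nominal(small_static_patient,
                                             static_weekly_wc):
    """1 mm residual shifts cannot pull the deep boost core out of the high
    dose: voxmin ~ nominal well inside the target."""
    wc = static_weekly_wc
    core = ndimage.binary_erosion(
        small_static_patient.planning_structures["ctv_high"], iterations=2)
    assert (wc.voxmin.values[core] >= 0.9 * wc.nominal.values[core]).all()


def test_accumulate_static_course_equals_planning(small_static_patient,
                                                  small_plan):
    p = small_static_patient
    acc = accumulate_course(small_plan, p, NO_ERROR_COURSE)
    calc = DoseCalculator(p.planning)
    tables = calc.make_tables(small_plan)
    g = p.grid
    pts = np.stack([c.ravel() for c in g.coordinate_grids()], axis=1)
    from anatrobust.dose_engine import Scenario
    planning_dose = calc.table_dose_at_points(
        tables, Scenario("planning"), pts).reshape(g.shape)
    assert np.allclose(acc.nominal.values, planning_dose,
                       atol=0.02 * planning_dose.max())
    assert np.allclose(acc.voxmin.values, acc.voxmax.values)


def test_accumulate_single_week_degenerate(small_patient, small_plan):
    course = CourseSpec(week_fraction_weights=(35, 0, 0, 0, 0, 0),
                        residual_setup_mm=0.0, range_frac=0.0)
    acc = accumulate_course(small_plan, small_patient, course, align=False)
    calc = DoseCalculator(small_patient.weekly[0][0])
    tables = calc.make_tables(small_plan)
    g = small_patient.grid
    pts = np.stack([c.ravel() for c in g.coordinate_grids()], axis=1)
    from anatrobust.dose_engine import Scenario
    week1 = DoseGrid(calc.table_dose_at_points(
        tables, Scenario("vct"), pts).reshape(g.shape), g)
    expected = warp_to_planning(week1, small_patient.true_dvfs[0])
    assert np.allclose(acc.nominal.values, expected.values, atol=1e-6)


def test_accumulate_matches_weighted_sum_oracle(small_patient, small_plan):
    course = CourseSpec(residual_setup_mm=0.0, range_frac=0.0)
    acc = accumulate_course(small_plan, small_patient, course, align=False)
    oracle = np.zeros(small_patient.grid.shape)
    for w in range(6):
        calc = DoseCalculator(small_patient.weekly[w][0])
        tables = calc.make_tables(small_plan)
        g = small_patient.grid
        pts = np.stack([c.ravel() for c in g.coordinate_grids()], axis=1)
        from anatrobust.dose_engine import Scenario
        dose = DoseGrid(calc.table_dose_at_points(
            tables, Scenario("vct"), pts).reshape(g.shape), g)
        warped = warp_to_planning(dose, small_patient.true_dvfs[w]).values
        oracle += course.week_fraction_weights[w] / 35.0 * warped
    assert np.allclose(acc.nominal.values, oracle, atol=1e-6)


def test_channel_ordering_after_accumulation(small_patient, small_plan):
    course = CourseSpec(week_fraction_weights=(10, 5, 5, 5, 5, 5))
    acc = accumulate_course(small_plan, small_patient, course, align=False)
    assert (acc.voxmin.values <= acc.nominal.values + 1e-6).all()
    assert (acc.nominal.values <= acc.voxmax.values + 1e-6).all()
    # convexity: the accumulated body-mean is a convex combination of the
    # planning-frame (warped) weekly body-means
    body = small_patient.planning_structures["body"]
    warped_means = [
        warp_to_planning(wc.nominal, dvf).values[body].mean()
        for wc, dvf in zip(acc.per_week, small_patient.true_dvfs)]
    acc_mean = acc.nominal.values[body].mean()
    assert min(warped_means) - 1e-6 <= acc_mean <= max(warped_means) + 1e-6


def test_point_sampled_accumulation_matches_grid_path(small_patient,
                                                      small_plan):
    course = CourseSpec()
    acc = accumulate_course(small_plan, small_patient, course)
    g = small_patient.grid
    mask = small_patient.planning_structures["ctv_high"]
    pts = g.index_to_world(np.argwhere(mask))
    ch = accumulate_course_at_points(small_plan, small_patient, pts, course)
    scale = acc.nominal.values.max()
    assert np.allclose(ch["nominal"], acc.nominal.values[mask],
                       atol=0.02 * scale)
    assert np.allclose(ch["voxmin"], acc.voxmin.values[mask],
                       atol=0.02 * scale)
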