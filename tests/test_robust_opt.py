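import numpy as np
import pytest

from anatrobust.dose_engine import Scenario, Spot, SpotPlan
from anatrobust.grids import DoseGrid
from anatrobust.robust_opt import (
    InfluenceStack,
    ObjectiveSpec,
    ObjectiveTerm,
    OptimizerConfig,
    add_normal_tissue_ring,
    composite_objective,
    default_objective,
    optimize,
)
from anatrobust.scenario_eval import ScenarioSet


@pytest.fixture()
def water_setup(water_box, sphere_structures):
    spots = [Spot(0, 0.0, u, v, 55.0, 5.0)
             for u in (-8.0, 0.0, 8.0) for v in (-8.0, 0.0, 8.0)]
    plan = SpotPlan((0.0,), spots, np.ones(len(spots)))
    return water_box, sphere_structures, plan


# -- composite objective ---------------------------------------------------

def test_objective_zero_at_feasible_point(water_box, sphere_structures):
    g = water_box.grid
    dose = DoseGrid(np.full(g.shape, 60.0), g)
    spec = ObjectiveSpec([ObjectiveTerm("target", "min_dose", 60.0, 10, True),
                          ObjectiveTerm("target", "max_dose", 60.0, 10, True)])
    assert composite_objective(dose, sphere_structures, spec) == 0.0


def test_objective_closed_form_underdose(water_box, sphere_structures):
    level, w = 60.0, 7.0
    dose = DoseGrid(np.full(water_box.grid.shape, 0.95 * level),
                    water_box.grid)
    spec = ObjectiveSpec([ObjectiveTerm("target", "min_dose", level, w, True)])
    assert composite_objective(dose, sphere_structures, spec) == pytest.approx(
        w * (0.05 * level) ** 2)


def test_objective_matches_per_voxel_summation_oracle(water_box,
                                                      sphere_structures):
    rng = np.random.default_rng(0)
    g = water_box.grid
    dose = DoseGrid(rng.uniform(0, 70, g.shape), g)
    spec = ObjectiveSpec([
        ObjectiveTerm("target", "min_dose", 60.0, 3.0, True),
        ObjectiveTerm("target", "max_dose", 65.0, 2.0, True),
        ObjectiveTerm("oar", "mean", 0.0, 1.5, False),
        ObjectiveTerm("oar", "uniform", 20.0, 0.5, True),
    ])
    total = 0.0
    for term in spec.terms:  # independent per-voxel loop
        vals = dose.values[sphere_structures[term.structure]]
        acc = 0.0
        for v in vals.ravel():
            if term.kind == "min_dose":
                acc += max(term.level_gy - v, 0.0) ** 2
            elif term.kind == "max_dose":
                acc += max(v - term.level_gy, 0.0) ** 2
            elif term.kind == "uniform":
                acc += (v - term.level_gy) ** 2
            else:
                acc += v
        total += term.weight * acc / vals.size
    assert composite_objective(dose, sphere_structures, spec) == pytest.approx(
        total)


def test_objective_missing_structure(water_box, sphere_structures):
    spec = ObjectiveSpec([ObjectiveTerm("nope", "mean", 0.0, 1.0, False)])
    dose = DoseGrid(np.zeros(water_box.grid.shape), water_box.grid)
    with pytest.raises(KeyError):
        composite_objective(dose, sphere_structures, spec)


def test_term_validation():
    with pytest.raises(ValueError):
        ObjectiveTerm("x", "median", 1.0, 1.0, True)
    with pytest.raises(ValueError):
        ObjectiveTerm("x", "mean", 1.0, 0.0, True)


# -- optimizer -------------------------------------------------------------

def _toy_problem(water_box, sphere_structures):
    spots = [Spot(0, 0.0, -6.0, 0.0, 55.0, 6.0),
             Spot(0, 0.0, 6.0, 0.0, 55.0, 6.0)]
    plan = SpotPlan((0.0,), spots, np.ones(2))
    spec = ObjectiveSpec([ObjectiveTerm("target", "uniform", 60.0, 1.0, True)])
    scens = ScenarioSet([Scenario("a", (2.0, 0, 0), 1.0),
                         Scenario("a", (-2.0, 0, 0), 1.0),
                         Scenario("a", (0, 0, 0), 0.97)],
                        "optimization", 2.0, 0.03)
    anat = {"a": (water_box, sphere_structures)}
    return plan, spec, scens, anat


def test_minimax_matches_exhaustive_grid_search(water_box, sphere_structures):
    """2-spot / 3-scenario toy: optimizer within 1% of brute-force search."""
    plan, spec, scens, anat = _toy_problem(water_box, sphere_structures)
    cfg = OptimizerConfig(max_iter=400)
    res = optimize(plan, anat, scens, spec, cfg)
    stack = InfluenceStack(plan, anat, scens, spec, cfg)

    def full(wv):
        d = stack.doses(np.asarray(wv, float))
        f, fn = stack.objectives(d)
        return f.max() + fn

    best = np.inf
    for w1 in np.linspace(0, 200, 101):
        for w2 in np.linspace(0, 200, 101):
            best = min(best, full([w1, w2]))
    assert res.trace[-1] <= best * 1.01
    assert all(b <= a + 1e-9 for a, b in zip(res.trace, res.trace[1:]))


def test_trace_nonincreasing_and_final_not_worse(water_setup):
    water_box, ss, plan = water_setup
    spec = ObjectiveSpec([ObjectiveTerm("target", "min_dose", 60, 10, True),
                          ObjectiveTerm("oar", "mean", 0.0, 1.0, False)])
    scens = ScenarioSet([Scenario("a", tuple(s), rho)
                         for s in ((1.0, 0, 0), (0, -1.0, 0))
                         for rho in (0.97, 1.03)], "optimization", 1.0, 0.03)
    res = optimize(plan, {"a": (water_box, ss)}, scens, spec,
                   OptimizerConfig(max_iter=60,
                                   exclude_targets_from_mean=False))
    assert all(b <= a + 1e-9 for a, b in zip(res.trace, res.trace[1:]))
    assert res.trace[-1] <= res.trace[0]
    assert (res.weights >= 0).all()


def test_duplicate_scenarios_change_nothing(water_box, sphere_structures):
    plan, spec, scens, anat = _toy_problem(water_box, sphere_structures)
    res1 = optimize(plan, anat, scens, spec, OptimizerConfig(max_iter=150))
    dup = ScenarioSet(scens.scenarios + scens.scenarios, "optimization",
                      2.0, 0.03)
    res2 = optimize(plan, anat, dup, spec, OptimizerConfig(max_iter=150))
    assert np.allclose(res1.weights, res2.weights, rtol=1e-6, atol=1e-9)


def test_single_scenario_equals_weighted_least_squares(water_box,
                                                       sphere_structures):
    """With one scenario the minimax problem is a nonnegative least-squares
    fit; the solution matches an independent bound-constrained solve."""
    spots = [Spot(0, 0.0, u, 0.0, 55.0, 6.0) for u in (-8.0, 0.0, 8.0)]
    plan = SpotPlan((0.0,), spots, np.ones(3))
    spec = ObjectiveSpec([ObjectiveTerm("target", "uniform", 60.0, 1.0,
                                        True)])
    scens = ScenarioSet([Scenario("a", (0.5, 0, 0), 1.0)], "optimization",
                        0.5, 0.0)
    anat = {"a": (water_box, sphere_structures)}
    cfg = OptimizerConfig(max_iter=800, rel_tol=1e-12)
    res = optimize(plan, anat, scens, spec, cfg)

    stack = InfluenceStack(plan, anat, scens, spec, cfg)
    from scipy import optimize as sopt
    lam = cfg.lambda_nominal

    def fun(wv):
        d = stack.doses(np.maximum(wv, 0))
        f, fn = stack.objectives(d)
        return f.max() + lam * fn

    ref = sopt.minimize(fun, np.full(3, 50.0), method="Nelder-Mead",
                        options=dict(xatol=1e-10, fatol=1e-14,
                                     maxiter=5000))
    assert res.trace[-1] == pytest.approx(ref.fun, rel=1e-6)


def test_single_spot_closed_form_weight(water_box, sphere_structures):
    """One spot, one uniform term: optimum is the analytic least-squares
    weight  w* = sum(a*L) / sum(a^2)  over the structure's voxels."""
    spot = Spot(0, 0.0, 0.0, 0.0, 55.0, 12.0)
    plan = SpotPlan((0.0,), [spot], np.ones(1))
    spec = ObjectiveSpec([ObjectiveTerm("target", "uniform", 60.0, 1.0,
                                        True)])
    scens = ScenarioSet([Scenario("a")], "optimization", 0.0, 0.0)
    anat = {"a": (water_box, sphere_structures)}
    cfg = OptimizerConfig(max_iter=600, rel_tol=1e-12)
    res = optimize(plan, anat, scens, spec, cfg)
    stack = InfluenceStack(plan, anat, scens, spec, cfg)
    a = np.asarray(stack.matrix[stack.row_slices[0][1]], float).ravel()
    w_star = 60.0 * a.sum() / (a ** 2).sum()
    assert res.weights[0] == pytest.approx(w_star, rel=1e-4)


def test_normal_tissue_ring_geometry(small_static_patient):
    ss = add_normal_tissue_ring(small_static_patient.planning_structures,
                                guard_vox=2, width_vox=3)
    ring = ss["normal_tissue"]
    targets = ss["ctv_high"] | ss["ctv_low"]
    assert ring.any()
    assert not (ring & targets).any()


def test_default_objective_structure():
    spec = default_objective()
    robust = {t.structure for t in spec.robust_terms()}
    assert {"ctv_high", "ctv_low", "brainstem", "spinal_cord"} <= robust
    # parallel organs are nominal-only mean terms
    for t in spec.terms:
        if t.kind == "mean":
            assert not t.robust


def test_larger_uncertainty_cannot_improve_nominal_optimum(
        water_box, sphere_structures):
    """Monotone robustness cost: the nominal-scenario objective achieved
    under 3 mm scenarios is no better than under 1 mm scenarios."""
    from anatrobust.scenario_eval import enumerate_setup_shifts

    spots = [Spot(0, 0.0, u, v, 55.0, 6.0)
             for u in (-10.0, 0.0, 10.0) for v in (-10.0, 0.0, 10.0)]
    plan = SpotPlan((0.0,), spots, np.ones(len(spots)))
    spec = ObjectiveSpec([ObjectiveTerm("target", "uniform", 60.0, 1.0, True),
                          ObjectiveTerm("oar", "max_dose", 20.0, 2.0, True)])
    nominal_objs = {}
    for mm in (1.0, 3.0):
        scens = ScenarioSet(
            [Scenario("a", tuple(s), rho)
             for s in enumerate_setup_shifts(mm)[:6]
             for rho in (0.97, 1.03)], "optimization", mm, 0.03)
        res = optimize(plan, {"a": (water_box, sphere_structures)}, scens,
                       spec, OptimizerConfig(max_iter=200))
        nominal_objs[mm] = res.nominal_objective
    assert nominal_objs[3.0] >= nominal_objs[1.0] - 1e-6
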