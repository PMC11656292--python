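"""Minimax robust spot-weight optimization over multi-anatomy scenarios.

The optimizer minimizes

    F(w) = max_s f_s(w) + lambda * f_nom(w),      w >= 0,

where ``s`` runs over the strategy's error scenarios (every included anatomy
crossed with the 14 x 2 setup/range errors), ``f_s`` is a composite dose
objective of the robust terms evaluated on scenario ``s``'s anatomy and
contours, and ``f_nom`` averages the full objective (robust terms plus
nominal-only mean-dose terms) over the error-free scenario of each anatomy.

The nonsmooth max is handled by a log-sum-exp smoothing with temperature
annealing: search directions come from the smoothed gradient, step
acceptance and the reported trace use the true worst case, so the trace is
nonincreasing by construction and the solution approaches the exact minimax
as the temperature is lowered.  Nonnegativity is kept by projection.  All
per-spot scenario doses (the influence matrices) are precomputed once; the
inner loop performs only matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dose_engine import (
    DoseCalculator,
    EngineConfig,
    Scenario,
    SpotPlan,
)
from .grids import DoseGrid, StructureSet, VoxelGrid
from .metrics import PRESCRIPTION_HIGH, PRESCRIPTION_LOW
from .scenario_eval import ScenarioSet

log = logging.getLogger(__name__)

QUADRATIC_KINDS = ("min_dose", "max_dose", "uniform")


@dataclass(frozen=True)
class ObjectiveTerm:
    structure: str
    kind: str          # min_dose | max_dose | uniform | mean
    level_gy: float    # target / threshold dose (ignored for mean terms)
    weight: float
    robust: bool       # robust terms enter every error scenario

    def __post_init__(self):
        if self.kind not in QUADRATIC_KINDS + ("mean",):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("term weight must be positive")


@dataclass
class ObjectiveSpec:
    terms: list[ObjectiveTerm]

    def robust_terms(self) -> list[ObjectiveTerm]:
        return [t for t in self.terms if t.robust]

    def structures(self, robust_only: bool = False) -> list[str]:
        seen = []
        for t in self.terms:
            if robust_only and not t.robust:
                continue
            if t.structure not in seen:
                seen.append(t.structure)
        return seen


def default_objective() -> ObjectiveSpec:
    """Composite objective derived from the clinical goal sheet.

    CTV coverage terms target each prescription dose with dominant weight,
    serial-organ ceilings sit below their hard limits, and parallel organs
    carry linear mean-dose terms that only the nominal scenario evaluates.
    """
    t = []
    t.append(ObjectiveTerm("ctv_high", "min_dose", PRESCRIPTION_HIGH,
                           300.0, True))
    t.append(ObjectiveTerm("ctv_high", "max_dose",
                           1.05 * PRESCRIPTION_HIGH, 60.0, True))
    t.append(ObjectiveTerm("ctv_low", "min_dose", PRESCRIPTION_LOW,
                           300.0, True))
    t.append(ObjectiveTerm("ctv_low", "max_dose", 66.0, 4.0, True))
    t.append(ObjectiveTerm("brainstem", "max_dose", 60.0, 10.0, True))
    t.append(ObjectiveTerm("spinal_cord", "max_dose", 50.0, 10.0, True))
    t.append(ObjectiveTerm("optic", "max_dose", 56.0, 4.0, True))
    t.append(ObjectiveTerm("normal_tissue", "max_dose", 55.0, 1.5, True))
    for organ, w in [("parotid_l", 0.5), ("parotid_r", 0.5),
                     ("submandibular", 0.5), ("oral_cavity", 0.4),
                     ("pcm_superior", 0.1), ("pcm_medius", 0.4),
                     ("pcm_inferior", 0.4)]:
        t.append(ObjectiveTerm(organ, "mean", 0.0, w, False))
    return ObjectiveSpec(t)


@dataclass
class OptimizerConfig:
    max_iter: int = 500
    rel_tol: float = 1e-5
    patience: int = 10
    lambda_nominal: float = 1.0
    temperatures: tuple[float, ...] = (0.03, 0.005)  # x initial scale
    sample_stride: int = 1      # structure-voxel subsampling for the
                                # objective point sets (1 = every voxel)
    max_points_per_structure: int = 100000
    #: evaluate mean-dose OAR terms on the organ volume outside the targets
    #: (overlapping voxels are owned by the CTV coverage terms); evaluation
    #: metrics always use the full organ
    exclude_targets_from_mean: bool = True
    verbose: bool = False


@dataclass
class OptimizationResult:
    weights: np.ndarray
    trace: list[float]
    converged: bool
    scenario_objectives: dict[int, float]
    nominal_objective: float

    @property
    def worst_case(self) -> float:
        if not self.scenario_objectives:
            return self.nominal_objective
        return max(self.scenario_objectives.values())


# --------------------------------------------------------------------------
# composite objective on full dose grids (reference path)
# --------------------------------------------------------------------------

def composite_objective(dose: DoseGrid, structures: StructureSet,
                        spec: ObjectiveSpec,
                        robust_only: bool = False) -> float:
    """Evaluate the composite objective on a full dose grid.

    One-sided quadratic penalties are averaged over each structure's voxels
    (in Gy^2); mean-dose terms contribute weight x mean dose (Gy).
    """
    total = 0.0
    d = dose.values
    for term in spec.terms:
        if robust_only and not term.robust:
            continue
        if term.structure not in structures:
            raise KeyError(f"missing structure {term.structure!r}")
        mask = structures[term.structure]
        if not mask.any():
            raise ValueError(f"structure {term.structure!r} is empty")
        total += _term_value(term, d[mask])
    return total


def _term_value(term: ObjectiveTerm, d: np.ndarray) -> float:
    if term.kind == "min_dose":
        return term.weight * float(np.mean(np.clip(term.level_gy - d, 0,
                                                   None) ** 2))
    if term.kind == "max_dose":
        return term.weight * float(np.mean(np.clip(d - term.level_gy, 0,
                                                   None) ** 2))
    if term.kind == "uniform":
        return term.weight * float(np.mean((d - term.level_gy) ** 2))
    return term.weight * float(np.mean(d))


def _term_grad(term: ObjectiveTerm, d: np.ndarray) -> np.ndarray:
    n = d.size
    if term.kind == "min_dose":
        return term.weight * (-2.0 / n) * np.clip(term.level_gy - d, 0, None)
    if term.kind == "max_dose":
        return term.weight * (2.0 / n) * np.clip(d - term.level_gy, 0, None)
    if term.kind == "uniform":
        return term.weight * (2.0 / n) * (d - term.level_gy)
    return np.full(n, term.weight / n)


# --------------------------------------------------------------------------
# sampled influence workspace
# --------------------------------------------------------------------------

def _structure_points(mask: np.ndarray, grid, stride: int, cap: int
                      ) -> np.ndarray:
    """World coordinates of (possibly subsampled) structure voxels.

    Subsampling is surface-weighted: boundary voxels (where coverage and
    falloff are decided) are kept at a denser stride than the interior,
    within a total budget of ``cap`` points.
    """
    from scipy import ndimage as ndi

    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty structure mask in objective")
    n = idx.shape[0]
    if max(stride, int(np.ceil(n / cap))) <= 1:
        return grid.index_to_world(idx)
    surface = mask & ~ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(3, 1))
    surf_idx = np.argwhere(surface)
    int_idx = np.argwhere(mask & ~surface)
    s_budget = max(int(0.7 * cap), 1)
    i_budget = max(cap - min(surf_idx.shape[0], s_budget), 1)
    s_step = max(1, int(np.ceil(surf_idx.shape[0] / s_budget)))
    i_step = max(stride, int(np.ceil(int_idx.shape[0] / i_budget)))
    picked = [surf_idx[::s_step]]
    if int_idx.size:
        picked.append(int_idx[::i_step])
    return grid.index_to_world(np.concatenate(picked, axis=0))


class _AnatomyBlock:
    """Objective point sets and term slices for one anatomy."""

    def __init__(self, anatomy_id: str, image: VoxelGrid,
                 structures: StructureSet, spec: ObjectiveSpec,
                 cfg: OptimizerConfig, engine_cfg: EngineConfig | None):
        self.anatomy_id = anatomy_id
        self.calc = DoseCalculator(image, engine_cfg)
        self.structures = structures
        grid = image.grid

        targets = None
        if cfg.exclude_targets_from_mean and "ctv_high" in structures:
            targets = structures["ctv_high"]
            if "ctv_low" in structures:
                targets = targets | structures["ctv_low"]

        def build(term_list):
            pts, slices, start = [], [], 0
            for term in term_list:
                mask = structures[term.structure]
                if term.kind == "mean" and targets is not None:
                    outside = mask & ~targets
                    if outside.any():
                        mask = outside
                p = _structure_points(mask, grid, cfg.sample_stride,
                                      cfg.max_points_per_structure)
                pts.append(p)
                slices.append((term, slice(start, start + p.shape[0])))
                start += p.shape[0]
            return (np.concatenate(pts, axis=0) if pts
                    else np.zeros((0, 3))), slices

        self.robust_pts, self.robust_slices = build(spec.robust_terms())
        self.all_pts, self.all_slices = build(spec.terms)

    def objective_from_dose(self, d: np.ndarray, slices) -> float:
        return sum(_term_value(term, d[sl]) for term, sl in slices)

    def grad_from_dose(self, d: np.ndarray, slices) -> np.ndarray:
        g = np.zeros_like(d)
        for term, sl in slices:
            g[sl] += _term_grad(term, d[sl])
        return g


class InfluenceStack:
    """Stacked per-scenario influence rows for one strategy's optimization.

    Rows are the concatenation of every error scenario's robust-objective
    points followed by every anatomy's nominal-scenario points; a single
    matrix product against the weights yields all scenario doses at once.
    """

    def __init__(self, plan: SpotPlan,
                 anatomies: dict[str, tuple[VoxelGrid, StructureSet]],
                 scenario_set: ScenarioSet, spec: ObjectiveSpec,
                 cfg: OptimizerConfig,
                 engine_cfg: EngineConfig | None = None):
        self.spec = spec
        self.cfg = cfg
        self.blocks = {
            aid: _AnatomyBlock(aid, img, ss, spec, cfg, engine_cfg)
            for aid, (img, ss) in anatomies.items()}
        self.scenarios = list(scenario_set.scenarios)
        self.anatomy_ids = list(anatomies)
        self.row_slices: list[tuple[str, slice]] = []
        self.nominal_slices: list[tuple[str, slice]] = []
        start = 0
        for sc in self.scenarios:
            n = self.blocks[sc.anatomy_id].robust_pts.shape[0]
            self.row_slices.append((sc.anatomy_id, slice(start, start + n)))
            start += n
        for aid in self.anatomy_ids:
            n = self.blocks[aid].all_pts.shape[0]
            self.nominal_slices.append((aid, slice(start, start + n)))
            start += n
        self.matrix = np.empty((start, len(plan.spots)), dtype=np.float32)
        for sc, (aid, sl) in zip(self.scenarios, self.row_slices):
            block = self.blocks[aid]
            self.matrix[sl] = block.calc.influence(plan, sc, block.robust_pts)
        for aid, sl in self.nominal_slices:
            block = self.blocks[aid]
            self.matrix[sl] = block.calc.influence(plan, Scenario(aid),
                                                   block.all_pts)

    # -- objective machinery -------------------------------------------------
    def doses(self, w: np.ndarray) -> np.ndarray:
        return self.matrix @ w.astype(np.float32)

    def objectives(self, d: np.ndarray
                   ) -> tuple[np.ndarray, float]:
        """Per-error-scenario objectives and the averaged nominal objective."""
        f = np.empty(len(self.scenarios))
        for i, (aid, sl) in enumerate(self.row_slices):
            block = self.blocks[aid]
            f[i] = block.objective_from_dose(
                d[sl].astype(float), block.robust_slices)
        f_nom = 0.0
        for aid, sl in self.nominal_slices:
            block = self.blocks[aid]
            f_nom += block.objective_from_dose(
                d[sl].astype(float), block.all_slices)
        return f, f_nom / max(len(self.nominal_slices), 1)

    def gradient(self, d: np.ndarray, softmax_w: np.ndarray,
                 lam: float) -> np.ndarray:
        r = np.zeros(self.matrix.shape[0], dtype=np.float32)
        for i, (aid, sl) in enumerate(self.row_slices):
            if softmax_w[i] < 1e-8:
                continue
            block = self.blocks[aid]
            r[sl] = softmax_w[i] * block.grad_from_dose(
                d[sl].astype(float), block.robust_slices)
        n_nom = max(len(self.nominal_slices), 1)
        for aid, sl in self.nominal_slices:
            block = self.blocks[aid]
            r[sl] = (lam / n_nom) * block.grad_from_dose(
                d[sl].astype(float), block.all_slices)
        return (self.matrix.T @ r).astype(float)


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

def optimize(plan: SpotPlan,
             anatomies: dict[str, tuple[VoxelGrid, StructureSet]],
             scenario_set: ScenarioSet, spec: ObjectiveSpec,
             cfg: OptimizerConfig | None = None,
             engine_cfg: EngineConfig | None = None,
             stack: InfluenceStack | None = None) -> OptimizationResult:
    """Minimax spot-weight optimization (projected descent on smoothed max).

    Deterministic: fixed uniform initialization scaled to the high-risk
    prescription, no randomness anywhere.
    """
    cfg = cfg or OptimizerConfig()
    if stack is None:
        stack = InfluenceStack(plan, anatomies, scenario_set, spec, cfg,
                               engine_cfg)
    n_spots = len(plan.spots)
    w = np.ones(n_spots)
    # scale start so the nominal mean dose over the first min-dose structure
    # approximates its level
    d0 = stack.doses(w)
    level = next((t.level_gy for t in spec.terms
                  if t.kind in ("min_dose", "uniform")), None)
    if level is not None:
        ref = []
        for aid, sl in stack.nominal_slices:
            block = stack.blocks[aid]
            for term, tsl in block.all_slices:
                if term.kind in ("min_dose", "uniform"):
                    ref.append(d0[sl][tsl])
                    break
            break
        if ref and np.mean(ref[0]) > 0:
            w *= level / float(np.mean(ref[0]))

    lam = cfg.lambda_nominal

    def true_objective(wv):
        d = stack.doses(wv)
        f, f_nom = stack.objectives(d)
        f_max = float(f.max()) if f.size else 0.0
        return f_max + lam * f_nom, d, f, f_nom

    F, d, f, f_nom = true_objective(w)
    trace = [F]
    best = dict(F=F, w=w.copy(), f=f, f_nom=f_nom)
    converged = False

    from scipy import optimize as _sopt

    def smoothed(wv, tau):
        """Log-sum-exp smoothed objective and gradient at temperature tau."""
        wv = np.maximum(wv, 0.0)
        dd = stack.doses(wv)
        ff, ffn = stack.objectives(dd)
        if ff.size:
            m = float(ff.max())
            z = np.exp((ff - m) / tau)
            lse = m + tau * np.log(z.sum())
            pi = z / z.sum()
        else:
            lse = 0.0
            pi = ff
        grad = stack.gradient(dd, pi, lam)
        # track the best iterate by the true (unsmoothed) worst case
        F_true = (float(ff.max()) if ff.size else 0.0) + lam * ffn
        if F_true < best["F"]:
            best.update(F=F_true, w=wv.copy(), f=ff, f_nom=ffn)
            trace.append(F_true)
            if cfg.verbose:
                log.info("tau=%.3g F=%.5g", tau, F_true)
        return lse + lam * ffn, grad

    # temperature annealing: each stage solves the smoothed problem with a
    # bound-constrained quasi-Newton method, warm-started from the best
    # iterate of the previous stage
    spread = float(f.max() - f.min()) if f.size else 0.0
    scale0 = max(spread, abs(F), 1.0)
    per_stage = max(cfg.max_iter // len(cfg.temperatures), 1)
    bounds = [(0.0, None)] * n_spots
    for tau_rel in cfg.temperatures:
        tau = max(tau_rel * scale0, 1e-9)
        res = _sopt.minimize(
            smoothed, best["w"], args=(tau,), jac=True, method="L-BFGS-B",
            bounds=bounds,
            options=dict(maxiter=per_stage, ftol=cfg.rel_tol * 1e-3,
                         gtol=1e-12, maxcor=20))
        converged = bool(res.success) or res.status == 1
    w = best["w"]
    f, f_nom = best["f"], best["f_nom"]
    scenario_objectives = {i: float(v) for i, v in enumerate(f)}
    return OptimizationResult(weights=w, trace=trace, converged=converged,
                              scenario_objectives=scenario_objectives,
                              nominal_objective=float(f_nom))


# --------------------------------------------------------------------------
# strategy-level planning
# --------------------------------------------------------------------------

def add_normal_tissue_ring(structures: StructureSet,
                           guard_vox: int = 2,
                           width_vox: int = 4) -> StructureSet:
    """Add a conformity shell around the targets to a structure set.

    The shell is the body tissue between ``guard_vox`` and ``guard_vox +
    width_vox`` voxels from either CTV; the guard band must sit beyond the
    lateral margin the robust scenarios demand, otherwise the dose-falloff
    objective fights the coverage terms.
    """
    from scipy import ndimage as ndi

    targets = structures["ctv_high"] | structures["ctv_low"]
    near = ndi.binary_dilation(targets, iterations=guard_vox + width_vox)
    guard = ndi.binary_dilation(targets, iterations=guard_vox)
    ring = structures["body"] & near & ~guard
    out = structures.copy()
    out.masks["normal_tissue"] = ring
    return out


@dataclass
class StrategyPlanResult:
    strategy: str
    plan: SpotPlan
    optimization: "OptimizationResult"
    planning_metrics: dict
    goals: object
    acceptable: bool
    planning_channels: dict | None = None  # per-channel dose at ROI points


def strategy_anatomies(planning: VoxelGrid, structures: StructureSet,
                       strategy, model=None
                       ) -> dict[str, tuple[VoxelGrid, StructureSet]]:
    """Assemble the anatomy dictionary a strategy optimizes over.

    Predicted anatomies come from the average model; their organ-at-risk and
    low-risk CTV contours are the propagated ones while the high-risk CTV is
    byte-identical to the planning contour.
    """
    from .anatomy_model import predict_anatomy
    from .scenario_eval import STRATEGIES

    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    spacing = min(planning.grid.spacing)
    guard = 2 + int(np.ceil(strategy.setup_mm / spacing))
    ss = (structures if "normal_tissue" in structures
          else add_normal_tissue_ring(structures, guard_vox=guard))
    anatomies: dict[str, tuple[VoxelGrid, StructureSet]] = {}
    for aid in strategy.anatomies:
        if aid == "planning":
            anatomies[aid] = (planning, ss)
        elif aid.startswith("predicted-week-"):
            if model is None:
                raise ValueError(
                    f"strategy {strategy.name} needs an average model")
            week = int(aid.rsplit("-", 1)[1])
            pred = predict_anatomy(model, planning, structures, week)
            anatomies[aid] = (pred.grid_image,
                              add_normal_tissue_ring(pred.structures,
                                                     guard_vox=guard))
        else:
            raise ValueError(f"unknown anatomy id {aid!r}")
    return anatomies


def plan_strategy(planning: VoxelGrid, structures: StructureSet,
                  strategy, model=None,
                  spec: ObjectiveSpec | None = None,
                  cfg: OptimizerConfig | None = None,
                  engine_cfg: EngineConfig | None = None,
                  lattice_kwargs: dict | None = None,
                  plan: SpotPlan | None = None) -> StrategyPlanResult:
    """Optimize one strategy and check the planning-stage clinical goals.

    The plan's spot lattice covers the union of both CTVs with a margin of
    the setup magnitude plus a penumbra allowance.  Planning-stage worst-case
    (voxmin/voxmax) dose is evaluated on the planning anatomy over the
    strategy's own 28 setup/range scenarios, and the goal sheet is applied;
    ``acceptable`` is False when any goal fails (the failed goals are listed
    in ``goals``).
    """
    from . import metrics as M
    from .dose_engine import make_spot_lattice
    from .scenario_eval import (STRATEGIES, enumerate_opt_scenarios,
                                enumerate_eval_scenarios)

    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    spec = spec or default_objective()
    cfg = cfg or OptimizerConfig()
    anatomies = strategy_anatomies(planning, structures, strategy, model)
    targets = structures["ctv_high"] | structures["ctv_low"]
    if plan is None:
        lk = dict(lateral_spacing_mm=13.0, layer_spacing_mm=10.0,
                  sigma0_mm=6.0)
        lk.update(lattice_kwargs or {})
        lk.setdefault("lateral_margin_mm", strategy.setup_mm + 6.0)
        plan = make_spot_lattice(planning, targets, **lk)
    scenario_set = enumerate_opt_scenarios(strategy)
    result = optimize(plan, anatomies, scenario_set, spec, cfg, engine_cfg)
    plan = plan.with_weights(result.weights)

    # planning-stage worst case on the planning anatomy, own error magnitudes
    calc = DoseCalculator(planning, engine_cfg)
    tables = calc.make_tables(plan, (1.0 - strategy.range_frac, 1.0,
                                     1.0 + strategy.range_frac))
    ss_ring = anatomies["planning"][1]
    pts, slices = _roi_points(ss_ring, planning.grid)
    nominal = calc.table_dose_at_points(tables, Scenario("planning"), pts)
    stack = np.stack([
        calc.table_dose_at_points(tables, sc, pts)
        for sc in enumerate_eval_scenarios(
            "planning", strategy.setup_mm, strategy.range_frac).scenarios]
        + [nominal])
    channels = {"nominal": nominal, "voxmin": stack.min(axis=0),
                "voxmax": stack.max(axis=0)}
    metric_table = channel_metrics(channels, slices,
                                   planning.grid.voxel_volume_cc)
    goals = M.goal_check(metric_table)
    return StrategyPlanResult(
        strategy=strategy.name, plan=plan, optimization=result,
        planning_metrics=metric_table, goals=goals,
        acceptable=goals.all_passed, planning_channels=channels)


def _roi_points(structures: StructureSet, grid
                ) -> tuple[np.ndarray, dict[str, slice]]:
    """All structure voxels (except body) as world points with slices."""
    pts, slices, start = [], {}, 0
    for name in structures.names():
        if name == "body":
            continue
        p = grid.index_to_world(np.argwhere(structures[name]))
        pts.append(p)
        slices[name] = slice(start, start + p.shape[0])
        start += p.shape[0]
    return np.concatenate(pts, axis=0), slices


def channel_metrics(channels: dict[str, np.ndarray],
                    slices: dict[str, slice],
                    voxel_volume_cc: float) -> dict:
    """DVH metric table from per-channel dose samples at structure voxels."""
    from . import metrics as M

    out: dict[tuple[str, str, str], float] = {}
    for ctv, rx in (("ctv_high", M.PRESCRIPTION_HIGH),
                    ("ctv_low", M.PRESCRIPTION_LOW)):
        if ctv not in slices:
            continue
        sl = slices[ctv]
        out[(ctv, "voxmin", "v94")] = M.vd_values(channels["voxmin"][sl],
                                                  0.94 * rx)
        out[(ctv, "nominal", "v94")] = M.vd_values(channels["nominal"][sl],
                                                   0.94 * rx)
        n = sl.stop - sl.start
        out[(ctv, "voxmax", "d2")] = M.d_cc_values(
            channels["voxmax"][sl], voxel_volume_cc,
            0.02 * n * voxel_volume_cc)
    for organ in ("brainstem", "spinal_cord", "optic"):
        if organ not in slices:
            continue
        sl = slices[organ]
        for ch in ("voxmax", "nominal"):
            out[(organ, ch, "d003cc")] = M.d_cc_values(
                channels[ch][sl], voxel_volume_cc, 0.03)
    for organ in ("parotid_l", "parotid_r", "submandibular", "oral_cavity",
                  "pcm_superior", "pcm_medius", "pcm_inferior", "thyroid"):
        if organ not in slices:
            continue
        sl = slices[organ]
        out[(organ, "nominal", "dmean")] = float(
            np.mean(channels["nominal"][sl]))
    return out
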