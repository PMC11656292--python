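"""Full-study orchestration: cohort -> models -> plans -> courses -> report.

For every validation patient an average model is trained on the rest of the
cohort (leave-one-out), the three planning strategies are optimized, the
same simulated treatment course (weekly anatomies + residual errors) is
accumulated for each plan, and the evaluation layer produces CTV coverage,
serial-organ and parallel-organ metrics, NTCP values and paired statistics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accumulate import CourseSpec, accumulate_course_at_points
from .anatomy_model import build_average_model
from .dose_engine import DoseCalculator, EngineConfig
from .grids import GridSpec
from . import metrics as M
from .phantom_cohort import DEFAULT_GRID, PatientTimeline, make_cohort
from .robust_opt import (
    OptimizerConfig,
    _roi_points,
    channel_metrics,
    plan_strategy,
)
from .scenario_eval import STRATEGIES

log = logging.getLogger(__name__)

PARALLEL_ORGANS = ("parotid_l", "parotid_r", "submandibular", "oral_cavity",
                   "pcm_superior", "pcm_medius", "pcm_inferior")


@dataclass
class StudyConfig:
    """Study-level settings; defaults mirror the emulated cohort design."""

    n_cohort: int = 20
    n_validation: int = 10
    master_seed: int = 7
    strategies: tuple[str, ...] = ("cRO3mm", "cRO1mm", "aRO1mm")
    grid: GridSpec = field(default_factory=lambda: DEFAULT_GRID)
    course: CourseSpec = field(default_factory=CourseSpec)
    population: dict | None = None
    opt: OptimizerConfig = field(default_factory=lambda: OptimizerConfig(
        max_iter=150, sample_stride=2, max_points_per_structure=300))
    engine: EngineConfig = field(default_factory=lambda: EngineConfig(
        straggling_floor_mm=5.0))
    lattice: dict = field(default_factory=lambda: dict(
        lateral_spacing_mm=13.0, layer_spacing_mm=10.0, sigma0_mm=5.0))

    def __post_init__(self):
        if not self.strategies:
            raise ValueError("at least one strategy required")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        if not 1 <= self.n_validation <= self.n_cohort:
            raise ValueError("n_validation must be within the cohort")


@dataclass
class StudyReport:
    per_patient: pd.DataFrame   # patient, strategy, structure, channel,
                                # metric, stage, value
    summary: pd.DataFrame       # per-strategy means of the key metrics
    pvalues: pd.DataFrame       # pairwise Wilcoxon p-values
    ntcp_reduction: pd.DataFrame
    failures: list[tuple[int, str, str]] = field(default_factory=list)


def evaluate_patient(patient: PatientTimeline, strategy_name: str,
                     config: StudyConfig, model=None,
                     plan_result=None, week_calcs=None) -> list[dict]:
    """Plan one strategy for one patient and simulate the course.

    Returns tidy metric rows for both the planning stage and the
    accumulated-course stage, including NTCP and the replanning flag.
    ``plan_result`` short-circuits the planning step with an existing
    :class:`~anatrobust.robust_opt.StrategyPlanResult` (the synthetic
    cohort shares one planning anatomy, so conventional plans are patient-
    independent); ``week_calcs`` shares per-week dose calculators across
    strategies.
    """
    rows: list[dict] = []
    res = plan_result
    if res is None:
        res = plan_strategy(patient.planning, patient.planning_structures,
                            strategy_name, model=model,
                            cfg=config.opt, engine_cfg=config.engine,
                            lattice_kwargs=dict(config.lattice))

    def add(stage, table):
        for (structure, channel, metric), value in table.items():
            rows.append(dict(strategy=strategy_name, stage=stage,
                             structure=structure, channel=channel,
                             metric=metric, value=value))

    add("planning", res.planning_metrics)
    rows.append(dict(strategy=strategy_name, stage="planning",
                     structure="plan", channel="", metric="acceptable",
                     value=float(res.acceptable)))
    rows.append(dict(strategy=strategy_name, stage="planning",
                     structure="plan", channel="", metric="worst_case_obj",
                     value=res.optimization.worst_case))

    # simulated course on the true weekly anatomies
    pts, slices = _roi_points(patient.planning_structures, patient.grid)
    channels = accumulate_course_at_points(
        res.plan, patient, pts, config.course, config.engine,
        week_calcs=week_calcs)
    acc_table = channel_metrics(channels, slices,
                                patient.grid.voxel_volume_cc)
    add("accumulated", acc_table)

    goal = M.goal_check(acc_table, accumulated=True)
    rows.append(dict(strategy=strategy_name, stage="accumulated",
                     structure="plan", channel="", metric="replan",
                     value=float(goal.replan)))

    # V94 ratios (accumulated voxmin / planning voxmin)
    for ctv in ("ctv_high", "ctv_low"):
        ratio = M.v94_ratio(acc_table[(ctv, "voxmin", "v94")],
                            res.planning_metrics[(ctv, "voxmin", "v94")])
        rows.append(dict(strategy=strategy_name, stage="accumulated",
                         structure=ctv, channel="voxmin",
                         metric="v94_ratio", value=ratio))

    # NTCP from accumulated nominal mean doses
    dm = {o: acc_table[(o, "nominal", "dmean")] for o in PARALLEL_ORGANS}
    ipsi = max(dm["parotid_l"], dm["parotid_r"])
    contra = min(dm["parotid_l"], dm["parotid_r"])
    ntcp_x = M.ntcp_xerostomia(dm["submandibular"], ipsi, contra)
    ntcp_d = M.ntcp_dysphagia(dm["oral_cavity"], dm["pcm_superior"],
                              dm["pcm_medius"], dm["pcm_inferior"],
                              pharynx=True)
    for name, val in (("ntcp_xerostomia", ntcp_x), ("ntcp_dysphagia", ntcp_d)):
        rows.append(dict(strategy=strategy_name, stage="accumulated",
                         structure="patient", channel="nominal",
                         metric=name, value=100.0 * val))
    return rows


def run_study(config: StudyConfig | None = None,
              cohort: list[PatientTimeline] | None = None) -> StudyReport:
    """Run the full comparison study.

    The cohort is generated from the master seed unless supplied; each of
    the first ``n_validation`` patients is evaluated with a model trained on
    the remaining cohort members (never on the patient itself).  Per-patient
    failures are isolated: the study continues and the failure is recorded.
    """
    config = config or StudyConfig()
    t0 = time.time()
    if cohort is None:
        log.info("generating cohort of %d patients", config.n_cohort)
        cohort = make_cohort(config.n_cohort, config.master_seed,
                             config.population, config.grid)
    all_rows: list[dict] = []
    failures: list[tuple[int, str, str]] = []
    needs_model = any("aRO" in s for s in config.strategies)
    # conventional (planning-anatomy-only) strategies see identical inputs
    # for every patient of the template cohort: plan them once
    shared_plans: dict[str, object] = {}
    for i in range(config.n_validation):
        patient = cohort[i]
        model = None
        if needs_model:
            training = cohort[:i] + cohort[i + 1:]
            model = build_average_model(training)
        week_calcs = [DoseCalculator(patient.weekly[w][0], config.engine)
                      for w in range(len(patient.weekly))]
        for strat in config.strategies:
            try:
                plan_result = shared_plans.get(strat)
                if plan_result is None and STRATEGIES[strat].anatomies == (
                        "planning",):
                    plan_result = plan_strategy(
                        patient.planning, patient.planning_structures,
                        strat, cfg=config.opt, engine_cfg=config.engine,
                        lattice_kwargs=dict(config.lattice))
                    shared_plans[strat] = plan_result
                rows = evaluate_patient(patient, strat, config, model=model,
                                        plan_result=plan_result,
                                        week_calcs=week_calcs)
            except Exception as exc:  # noqa: BLE001 - isolate per patient
                log.exception("patient %d strategy %s failed", i, strat)
                failures.append((i, strat, str(exc)))
                continue
            for r in rows:
                r["patient"] = i
            all_rows.extend(rows)
        log.info("patient %d done (%.1f s elapsed)", i, time.time() - t0)
    per_patient = pd.DataFrame(all_rows)
    summary, pvalues, reduction = summarize(per_patient, config.strategies)
    return StudyReport(per_patient, summary, pvalues, reduction, failures)


def summarize(per_patient: pd.DataFrame, strategies: tuple[str, ...]
              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort summary: strategy means, pairwise Wilcoxon tests and the
    per-patient NTCP reduction of the anatomy-aware strategy."""
    key_metrics = per_patient[
        (per_patient.metric.isin(["v94", "v94_ratio", "d003cc", "dmean",
                                  "ntcp_xerostomia", "ntcp_dysphagia",
                                  "replan"]))
    ]
    summary = (key_metrics
               .groupby(["stage", "structure", "channel", "metric",
                         "strategy"])["value"]
               .agg(["mean", "min", "max"])
               .reset_index())

    paired_metrics = []
    for organ in PARALLEL_ORGANS:
        paired_metrics.append(("accumulated", organ, "dmean"))
    paired_metrics += [("accumulated", "patient", "ntcp_xerostomia"),
                       ("accumulated", "patient", "ntcp_dysphagia")]
    prows = []
    for stage, structure, metric in paired_metrics:
        sel = per_patient[(per_patient.stage == stage)
                          & (per_patient.structure == structure)
                          & (per_patient.metric == metric)]
        wide = sel.pivot_table(index="patient", columns="strategy",
                               values="value")
        for a in strategies:
            for b in strategies:
                if a >= b or a not in wide or b not in wide:
                    continue
                try:
                    p = M.wilcoxon_paired(wide[a].values, wide[b].values)
                except (ValueError, Warning):
                    p = np.nan
                prows.append(dict(stage=stage, structure=structure,
                                  metric=metric, strategy_a=a, strategy_b=b,
                                  p_value=p))
    pvalues = pd.DataFrame(prows)

    reduction = pd.DataFrame()
    if {"cRO3mm", "aRO1mm"} <= set(strategies):
        sel = per_patient[per_patient.metric.isin(
            ["ntcp_xerostomia", "ntcp_dysphagia"])]
        wide = sel.pivot_table(index=["patient", "metric"],
                               columns="strategy", values="value")
        wide["reduction"] = wide["cRO3mm"] - wide["aRO1mm"]
        reduction = wide.reset_index()[["patient", "metric", "reduction"]]
    return summary, pvalues, reduction


def report_tables(report: StudyReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-patient and cohort CSV artifacts; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("per_patient", report.per_patient),
                     ("summary", report.summary),
                     ("wilcoxon", report.pvalues),
                     ("ntcp_reduction", report.ntcp_reduction)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    if report.failures:
        p = out / "failures.json"
        p.write_text(json.dumps(report.failures, indent=2))
        paths["failures"] = p
    return paths
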