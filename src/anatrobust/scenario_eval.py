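"""Uncertainty-scenario enumeration and worst-case dose reduction.

Setup errors are the conventional 14-direction set (6 face + 8 corner
directions, every vector scaled to the stated magnitude); range errors are
pure +-3% scalings.  Their cross product gives 28 error scenarios per
anatomy; the nominal (error-free) scenario is always carried separately.

Worst-case (voxmin/voxmax) distributions record the per-voxel minimum and
maximum dose over a scenario stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_engine import Scenario
from .grids import DoseGrid


@dataclass(frozen=True)
class StrategySpec:
    """A robust-optimization strategy: anatomies + uncertainty magnitudes."""

    name: str
    setup_mm: float
    range_frac: float
    #: anatomy ids included in the optimization scenario set
    anatomies: tuple[str, ...]


#: planning strategies compared in the study: conventional robust
#: optimization at 3 mm / 1 mm setup on the planning anatomy, and
#: anatomy-aware 1 mm adding predicted anatomies at weeks 1, 3 and 5
STRATEGIES: dict[str, StrategySpec] = {
    "cRO3mm": StrategySpec("cRO3mm", 3.0, 0.03, ("planning",)),
    "cRO1mm": StrategySpec("cRO1mm", 1.0, 0.03, ("planning",)),
    "aRO1mm": StrategySpec(
        "aRO1mm", 1.0, 0.03,
        ("planning", "predicted-week-1", "predicted-week-3",
         "predicted-week-5")),
}


@dataclass
class ScenarioSet:
    scenarios: list[Scenario]
    purpose: str                 # "optimization" | "evaluation"
    setup_magnitude: float
    range_magnitude: float

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)


@dataclass
class WorstCaseDose:
    voxmin: DoseGrid
    voxmax: DoseGrid
    nominal: DoseGrid


def enumerate_setup_shifts(magnitude_mm: float) -> np.ndarray:
    """The 14 setup-shift directions scaled to ``magnitude_mm``.

    Six axis-aligned (face) and eight body-diagonal (corner) directions,
    each normalized to the requested Euclidean length; deterministic order
    (faces first: +-x, +-y, +-z, then corners in sign-lexicographic order).
    """
    if magnitude_mm <= 0:
        raise ValueError("setup magnitude must be positive")
    dirs = []
    for axis in range(3):
        for sign in (+1.0, -1.0):
            e = np.zeros(3)
            e[axis] = sign
            dirs.append(e)
    for sx in (+1.0, -1.0):
        for sy in (+1.0, -1.0):
            for sz in (+1.0, -1.0):
                dirs.append(np.array([sx, sy, sz]) / np.sqrt(3.0))
    return np.asarray(dirs) * magnitude_mm


def enumerate_eval_scenarios(anatomy_id: str, setup_mm: float,
                             range_frac: float) -> ScenarioSet:
    """The 28 evaluation scenarios (14 shifts x 2 range errors) per anatomy.

    The nominal scenario is deliberately excluded; it is computed separately.
    """
    shifts = enumerate_setup_shifts(setup_mm)
    scenarios = [
        Scenario(anatomy_id, tuple(s), rho)
        for s in shifts
        for rho in (1.0 - range_frac, 1.0 + range_frac)
    ]
    return ScenarioSet(scenarios, "evaluation", setup_mm, range_frac)


def enumerate_opt_scenarios(strategy: str | StrategySpec) -> ScenarioSet:
    """Error scenarios entering the minimax objective for a strategy.

    Per included anatomy, 14 x 2 error scenarios; the per-anatomy nominal
    scenarios are appended by the optimizer as a separate weighted term.
    """
    if isinstance(strategy, str):
        try:
            strategy = STRATEGIES[strategy]
        except KeyError:
            raise ValueError(f"unknown strategy {strategy!r}; "
                             f"known: {sorted(STRATEGIES)}") from None
    scenarios = []
    for anatomy in strategy.anatomies:
        scenarios.extend(
            enumerate_eval_scenarios(anatomy, strategy.setup_mm,
                                     strategy.range_frac).scenarios)
    return ScenarioSet(scenarios, "optimization", strategy.setup_mm,
                       strategy.range_frac)


def nominal_scenarios(strategy: str | StrategySpec) -> list[Scenario]:
    """One error-free scenario per anatomy of the strategy."""
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    return [Scenario(a) for a in strategy.anatomies]


def worst_case(doses: list[DoseGrid], nominal: DoseGrid) -> WorstCaseDose:
    """Per-voxel min/max over a dose stack, with the nominal kept alongside."""
    if not doses:
        raise ValueError("need at least one dose distribution")
    grid = doses[0].grid
    stack = []
    for d in doses:
        if d.values.shape != grid.shape:
            raise ValueError("dose grids must share one shape")
        stack.append(d.values)
    arr = np.stack(stack)
    return WorstCaseDose(
        voxmin=DoseGrid(arr.min(axis=0), grid),
        voxmax=DoseGrid(arr.max(axis=0), grid),
        nominal=nominal,
    )


def worst_case_arrays(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """voxmin/voxmax over axis 0 of a raw scenario-dose stack."""
    return stack.min(axis=0), stack.max(axis=0)
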