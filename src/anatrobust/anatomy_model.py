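"""Population average-deformation model and anatomy prediction.

The model is the voxelwise arithmetic mean of the training patients' weekly
forward displacement fields (planning -> week).  Because synthetic patients
share one template frame, inter-patient correspondence is the identity; this
stands in for registration-based correspondence on real cohorts.

Prediction warps a new patient's planning image and contours through the mean
field for the requested week.  Contour rules follow the planning protocol for
anatomy-aware robust optimization: every organ at risk and the low-risk CTV
are propagated with the field; the high-risk CTV is copied unchanged from the
planning structure set so target coverage is never relaxed by the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (
    DisplacementField,
    GridSpec,
    StructureSet,
    VoxelGrid,
    invert_dvf,
    warp_scalar,
)
from .phantom_cohort import WEEKS, WEEK_FRACTIONS, PatientTimeline

#: structures that are never propagated but copied from planning
COPY_FROM_PLANNING = ("ctv_high",)


@dataclass
class AverageModel:
    """Mean weekly forward displacement fields on the template grid."""

    mean_dvfs: list[DisplacementField]  # index w-1 -> planning->week-w field
    n_train: int
    week_points: tuple[int, ...] = WEEK_FRACTIONS

    @property
    def grid(self) -> GridSpec:
        return self.mean_dvfs[0].grid


@dataclass
class PredictedAnatomy:
    week: int
    grid_image: VoxelGrid
    structures: StructureSet
    source_rule: dict[str, str]


def build_average_model(training: list[PatientTimeline]) -> AverageModel:
    """Voxelwise mean of the training patients' weekly forward DVFs."""
    if not training:
        raise ValueError("need at least one training patient")
    grid = training[0].grid
    for p in training:
        if p.grid.shape != grid.shape:
            raise ValueError("training patients must share one grid")
    mean_dvfs = []
    for w in WEEKS:
        acc = np.zeros((3,) + grid.shape)
        for p in training:
            acc += p.true_dvfs[w - 1].vectors
        mean_dvfs.append(DisplacementField(acc / len(training), grid))
    return AverageModel(mean_dvfs, n_train=len(training))


def predict_anatomy(model: AverageModel, planning: VoxelGrid,
                    structures: StructureSet, week: int) -> PredictedAnatomy:
    """Predict the week-``week`` anatomy of a patient from the average model.

    Only the patient's planning data enter the prediction; the patient's true
    weekly images are never read.
    """
    if week not in WEEKS:
        raise ValueError(f"week must be in {WEEKS}, got {week}")
    u = model.mean_dvfs[week - 1]
    if u.is_identity():
        image = planning.copy()
        masks = {n: m.copy() for n, m in structures.masks.items()}
    else:
        # the mean field maps planning->week; producing the week image needs
        # the pull-back (week->planning) map, i.e. the numerical inverse
        pullback = invert_dvf(u)
        image = VoxelGrid(
            warp_scalar(planning.values, pullback, order=1,
                        cval=float(planning.values.min())),
            planning.grid)
        masks = {}
        for name, m in structures.masks.items():
            if name in COPY_FROM_PLANNING:
                masks[name] = m.copy()
            else:
                masks[name] = warp_scalar(
                    m.astype(np.float32), pullback, order=0) > 0.5
    rule = {n: ("planning-copy" if n in COPY_FROM_PLANNING else "propagated")
            for n in masks}
    return PredictedAnatomy(week, image,
                            StructureSet(masks, planning.grid, rule), rule)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS)


def mean_surface_distance(mask_a: np.ndarray, mask_b: np.ndarray,
                          spacing) -> float:
    """Symmetric mean surface distance (mm) between two binary masks."""
    if not mask_a.any() or not mask_b.any():
        raise ValueError("empty structure mask")
    surf_a, surf_b = _surface(mask_a), _surface(mask_b)
    d_to_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    total = d_to_b[surf_a].sum() + d_to_a[surf_b].sum()
    return float(total / (surf_a.sum() + surf_b.sum()))


def loo_validate(cohort: list[PatientTimeline],
                 structures: tuple[str, ...] = ("parotid_l", "parotid_r"),
                 weeks: tuple[int, ...] = WEEKS) -> pd.DataFrame:
    """Leave-one-out validation of the average model.

    For each held-out patient the model is built on the remaining patients
    and its predicted contours are compared against the patient's true weekly
    contours via MSD; the no-model baseline compares the unwarped planning
    contour against the same truth.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two patients for leave-one-out")
    rows = []
    for i, held_out in enumerate(cohort):
        model = build_average_model(cohort[:i] + cohort[i + 1:])
        spacing = held_out.grid.spacing
        for week in weeks:
            pred = predict_anatomy(model, held_out.planning,
                                   held_out.planning_structures, week)
            true_ss = held_out.weekly[week - 1][1]
            for name in structures:
                rows.append({
                    "patient": i,
                    "week": week,
                    "structure": name,
                    "msd_model": mean_surface_distance(
                        pred.structures[name], true_ss[name], spacing),
                    "msd_no_model": mean_surface_distance(
                        held_out.planning_structures[name], true_ss[name],
                        spacing),
                })
    return pd.DataFrame(rows)
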