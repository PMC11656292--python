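"""Dose metrics, NTCP models, gamma index and paired statistics.

DVH metrics operate on a dose array and a binary mask sharing one grid:
``vd`` (percent volume at or above a dose level), ``d_percent`` (dose to the
hottest x% of the structure) and ``d_cc`` (dose to the hottest x cm^3),
with sub-voxel cutoffs resolved by linear interpolation along the sorted
cumulative-volume curve.

The NTCP models are multivariable logistic functions of accumulated mean
organ doses (in Gy over the full course): grade >= 2 xerostomia from the
submandibular and parotid mean doses, grade >= 2 dysphagia from the oral
cavity and pharyngeal-constrictor mean doses with a pharynx tumor-site term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
from scipy import stats

from .grids import GridSpec


# --------------------------------------------------------------------------
# DVH metrics
# --------------------------------------------------------------------------

def vd_values(values: np.ndarray, level_gy: float) -> float:
    """Percent of dose samples at or above ``level_gy``."""
    if values.size == 0:
        raise ValueError("empty structure mask")
    return 100.0 * float((values >= level_gy).sum()) / values.size


def vd(dose: np.ndarray, mask: np.ndarray, level_gy: float) -> float:
    """Percent of the structure's volume receiving at least ``level_gy``."""
    if not mask.any():
        raise ValueError("empty structure mask")
    return vd_values(dose[mask], level_gy)


def d_percent(dose: np.ndarray, mask: np.ndarray, grid: GridSpec,
              pct: float) -> float:
    """Dose to the hottest ``pct`` percent of the structure (e.g. D2)."""
    cc = pct / 100.0 * float(mask.sum()) * grid.voxel_volume_cc
    return d_cc(dose, mask, grid, cc)


def d_cc_values(values: np.ndarray, voxel_volume_cc: float,
                volume_cc: float) -> float:
    """Dose at the hottest ``volume_cc`` cm^3 of a sample of voxel doses.

    The k-th hottest voxel marks cumulative volume k * voxel_volume; the
    requested cutoff interpolates linearly between neighbouring voxels and
    clamps to the hottest voxel below one voxel volume.
    """
    vals = np.sort(np.asarray(values, dtype=float))[::-1]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    if volume_cc > vals.size * voxel_volume_cc + 1e-12:
        raise ValueError(
            f"requested {volume_cc} cc exceeds structure volume "
            f"{vals.size * voxel_volume_cc:.3f} cc")
    t = np.clip(volume_cc / voxel_volume_cc, 1.0, float(vals.size))
    return float(np.interp(t, np.arange(1, vals.size + 1), vals))


def d_cc(dose: np.ndarray, mask: np.ndarray, grid: GridSpec,
         volume_cc: float) -> float:
    """Dose to the hottest ``volume_cc`` cm^3 of the structure."""
    return d_cc_values(dose[mask], grid.voxel_volume_cc, volume_cc)


def mean_dose(dose: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("empty structure mask")
    return float(dose[mask].mean())


def v94_ratio(accumulated_v94: float, planning_v94: float) -> float:
    """Accumulated-to-planning ratio of V94 on the voxmin distribution."""
    if planning_v94 <= 0:
        raise ZeroDivisionError("planning V94 is zero")
    return accumulated_v94 / planning_v94


# --------------------------------------------------------------------------
# NTCP logistic models
# --------------------------------------------------------------------------

def _logistic(s: float) -> float:
    return 1.0 / (1.0 + math.exp(-s))


def ntcp_xerostomia(dmean_submandibular: float, dmean_ipsi_parotid: float,
                    dmean_contra_parotid: float) -> float:
    """NTCP of grade >= 2 patient-rated xerostomia (logistic in mean doses)."""
    for d in (dmean_submandibular, dmean_ipsi_parotid, dmean_contra_parotid):
        if d < 0:
            raise ValueError("mean doses must be nonnegative")
    s = (-2.2951
         + 0.0182 * dmean_submandibular
         + 0.0996 * (math.sqrt(dmean_ipsi_parotid)
                     + math.sqrt(dmean_contra_parotid)))
    return _logistic(s)


def ntcp_dysphagia(dmean_oral_cavity: float, dmean_pcm_superior: float,
                   dmean_pcm_medius: float, dmean_pcm_inferior: float,
                   pharynx: bool = True) -> float:
    """NTCP of grade >= 2 dysphagia (logistic in mean doses + site term)."""
    for d in (dmean_oral_cavity, dmean_pcm_superior, dmean_pcm_medius,
              dmean_pcm_inferior):
        if d < 0:
            raise ValueError("mean doses must be nonnegative")
    s = (-4.0536
         + 0.03 * dmean_oral_cavity
         + 0.0236 * dmean_pcm_superior
         + 0.0095 * dmean_pcm_medius
         + 0.0133 * dmean_pcm_inferior
         - 0.6281 * (1.0 if pharynx else 0.0))
    return _logistic(s)


# --------------------------------------------------------------------------
# gamma index
# --------------------------------------------------------------------------

def gamma_pass_rate(reference: np.ndarray, evaluated: np.ndarray,
                    grid: GridSpec, dta_mm: float = 2.0,
                    dd_frac: float = 0.02,
                    threshold_frac: float = 0.1) -> float:
    """Global 3-D gamma pass rate (percent) at voxel resolution.

    For every reference voxel above ``threshold_frac`` of the reference
    maximum, gamma^2 is minimized over all voxel-center offsets within a
    search radius of 3x the distance-to-agreement criterion; the dose
    difference is normalized to the global reference maximum.
    """
    if reference.shape != evaluated.shape:
        raise ValueError("dose grids must share one shape")
    ref_max = float(reference.max())
    include = reference >= threshold_frac * ref_max
    if not include.any():
        raise ValueError("no reference voxels above the dose threshold")
    spacing = grid.spacing_arr
    radius = 3.0 * dta_mm
    offsets = []
    ranges = [np.arange(-int(radius // s), int(radius // s) + 1)
              for s in spacing]
    for di in ranges[0]:
        for dj in ranges[1]:
            for dk in ranges[2]:
                r2 = ((di * spacing[0]) ** 2 + (dj * spacing[1]) ** 2
                      + (dk * spacing[2]) ** 2)
                if r2 <= radius ** 2:
                    offsets.append((di, dj, dk, r2))
    offsets.sort(key=lambda o: o[3])

    gamma2 = np.full(reference.shape, np.inf)
    norm = dd_frac * ref_max
    for di, dj, dk, r2 in offsets:
        dist_term = r2 / dta_mm ** 2
        if dist_term > 1.0 + 1e-9:
            # a larger offset can no longer turn gamma <= 1; pass/fail fixed
            break
        shifted = _shift_array(evaluated, (di, dj, dk))
        dd = (shifted - reference) / norm
        cand = dist_term + dd ** 2
        np.minimum(gamma2, cand, out=gamma2)
    rate = (gamma2[include] <= 1.0 + 1e-9).mean()
    return 100.0 * float(rate)


def _shift_array(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift with edge padding (NaN-free), pure integer roll-and-fill."""
    out = arr
    for axis, o in enumerate(offset):
        if o == 0:
            continue
        out = np.take(out, np.clip(np.arange(arr.shape[axis]) + o, 0,
                                   arr.shape[axis] - 1), axis=axis)
    return out


# --------------------------------------------------------------------------
# paired nonparametric test
# --------------------------------------------------------------------------

def wilcoxon_paired(values_a, values_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (zero-drop convention); tied absolute
    differences get average ranks.  For n <= 25 retained pairs the exact
    null distribution of the signed-rank sum is enumerated by dynamic
    programming; beyond that the normal approximation with tie correction
    is used.  Identical samples degenerate to p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    diff = diff[diff != 0.0]
    n = diff.size
    if n == 0:
        warnings.warn("all paired differences are zero; p-value degenerate")
        return 1.0
    ranks = stats.rankdata(np.abs(diff))
    w_plus = ranks[diff > 0].sum()
    if n <= 25:
        return _exact_signed_rank_p(ranks, w_plus)
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                         mode="approx")
    return float(res.pvalue)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by convolving the signed-rank sum distribution.

    Doubling the (possibly half-integer average) ranks makes them integers,
    so the 2^n equally likely sign assignments reduce to a polynomial
    product tracked on an integer lattice.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    lo_tail = counts[:w2 + 1].sum()
    hi_tail = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))


# --------------------------------------------------------------------------
# clinical goals
# --------------------------------------------------------------------------

@dataclass
class GoalResult:
    name: str
    value: float
    limit: float
    passed: bool


@dataclass
class GoalReport:
    goals: list[GoalResult] = field(default_factory=list)
    replan: bool = False

    @property
    def all_passed(self) -> bool:
        return all(g.passed for g in self.goals)

    def failed(self) -> list[str]:
        return [g.name for g in self.goals if not g.passed]


#: (structure, channel, metric, limit) — limits in Gy or percent
PRESCRIPTION_HIGH = 70.0
PRESCRIPTION_LOW = 54.25
V94_GOAL_PCT = 98.0
REPLAN_V94_PCT = 94.0
CTV_D2_LIMIT = 77.0  # 110% of the high prescription

SERIAL_LIMITS = {
    # structure: (voxmax D0.03cc limit, nominal D0.03cc limit)
    "brainstem": (68.0, 63.1),
    "spinal_cord": (58.5, 55.0),
    "optic": (64.0, 59.5),
}


def goal_check(metrics_by_key: dict[tuple[str, str, str], float],
               accumulated: bool = False) -> GoalReport:
    """Evaluate the clinical goals on a metric dictionary.

    ``metrics_by_key`` maps ``(structure, channel, metric)`` to a value,
    e.g. ``("ctv_high", "voxmin", "v94") -> 99.1`` (percent) or
    ``("brainstem", "voxmax", "d003cc") -> 47.2`` (Gy).  Missing required
    structures raise a KeyError naming the structure.  With
    ``accumulated=True`` the replan flag is set when a CTV V94(voxmin)
    falls below the replanning threshold.
    """
    report = GoalReport()

    def need(key):
        if key not in metrics_by_key:
            raise KeyError(f"missing metric {key[2]} for structure {key[0]} "
                           f"({key[1]} channel)")
        return metrics_by_key[key]

    for ctv in ("ctv_high", "ctv_low"):
        v = need((ctv, "voxmin", "v94"))
        report.goals.append(GoalResult(
            f"{ctv} V94(voxmin)>{V94_GOAL_PCT}", v, V94_GOAL_PCT,
            v > V94_GOAL_PCT))
        if accumulated and v < REPLAN_V94_PCT:
            report.replan = True
    for ctv in ("ctv_high", "ctv_low"):
        d2 = need((ctv, "voxmax", "d2"))
        report.goals.append(GoalResult(
            f"{ctv} D2(voxmax)<{CTV_D2_LIMIT}Gy", d2, CTV_D2_LIMIT,
            d2 < CTV_D2_LIMIT))
    for organ, (lim_wc, lim_nom) in SERIAL_LIMITS.items():
        dwc = need((organ, "voxmax", "d003cc"))
        report.goals.append(GoalResult(
            f"{organ} D0.03cc(voxmax)<{lim_wc}Gy", dwc, lim_wc, dwc < lim_wc))
        dnom = need((organ, "nominal", "d003cc"))
        report.goals.append(GoalResult(
            f"{organ} D0.03cc(nominal)<{lim_nom}Gy", dnom, lim_nom,
            dnom < lim_nom))
    return report
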