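import itertools
import math

import numpy as np
import pytest
import sympy

from anatrobust.grids import GridSpec
from anatrobust import metrics as M


@pytest.fixture()
def grid():
    return GridSpec((12, 12, 12), (3.0, 3.0, 3.0))


# -- Vd / Dcc --------------------------------------------------------------

def test_vd_saturation_and_floor(grid):
    mask = np.ones(grid.shape, bool)
    dose = np.full(grid.shape, 60.0)
    assert M.vd(dose, mask, 50.0) == 100.0
    assert M.vd(dose, mask, 0.0) == 100.0
    rng = np.random.default_rng(0)
    dose = rng.random(grid.shape)
    assert M.vd(dose, mask, 0.0) == 100.0


def test_vd_matches_counting_oracle(grid):
    rng = np.random.default_rng(1)
    dose = rng.uniform(0, 70, grid.shape)
    mask = rng.random(grid.shape) > 0.5
    level = 35.0
    count = sum(1 for v in dose[mask].ravel() if v >= level)
    assert M.vd(dose, mask, level) == pytest.approx(
        100.0 * count / mask.sum())


def test_vd_empty_mask(grid):
    with pytest.raises(ValueError):
        M.vd(np.zeros(grid.shape), np.zeros(grid.shape, bool), 1.0)


def test_dcc_uniform_and_single_voxel(grid):
    mask = np.zeros(grid.shape, bool)
    mask[2, 3, 4] = True
    dose = np.full(grid.shape, 44.0)
    vv = grid.voxel_volume_cc  # 0.027 cc at 3 mm
    assert M.d_cc(dose, mask, grid, vv) == 44.0
    mask2 = np.ones(grid.shape, bool)
    assert M.d_cc(dose, mask2, grid, 0.03) == 44.0
    assert M.d_percent(dose, mask2, grid, 2.0) == 44.0


def test_dcc_matches_sorted_interpolation_oracle(grid):
    rng = np.random.default_rng(2)
    dose = rng.uniform(0, 70, grid.shape)
    mask = rng.random(grid.shape) > 0.3
    vv = grid.voxel_volume_cc
    for cc in (0.03, 0.5, 2.0):
        vals = sorted(dose[mask], reverse=True)
        t = min(max(cc / vv, 1.0), len(vals))
        k = int(math.floor(t))
        if k >= len(vals):
            oracle = vals[-1]
        else:
            frac = t - k
            oracle = vals[k - 1] * (1 - frac) + vals[k] * frac
        assert M.d_cc(dose, mask, grid, cc) == pytest.approx(oracle)


def test_dcc_exceeding_volume_rejected(grid):
    mask = np.zeros(grid.shape, bool)
    mask[0, 0, 0] = True
    with pytest.raises(ValueError):
        M.d_cc(np.ones(grid.shape), mask, grid, 1.0)


def test_v94_ratio():
    assert M.v94_ratio(98.0, 98.0) == 1.0
    assert M.v94_ratio(97.0, 98.0) == pytest.approx(0.9898, abs=1e-4)
    with pytest.raises(ZeroDivisionError):
        M.v94_ratio(50.0, 0.0)


# -- NTCP ------------------------------------------------------------------

def _sympy_logistic(s_expr):
    return float((1 / (1 + sympy.exp(-s_expr))).evalf(50))


def test_ntcp_xerostomia_zero_dose():
    expected = _sympy_logistic(sympy.Rational(-22951, 10000))
    assert M.ntcp_xerostomia(0, 0, 0) == pytest.approx(expected, abs=1e-12)


def test_ntcp_logistic_midpoint():
    # choose doses so the linear predictor vanishes exactly
    # 0.0182 * d = 2.2951 with zero parotid dose
    d_sub = 2.2951 / 0.0182
    assert M.ntcp_xerostomia(d_sub, 0, 0) == pytest.approx(0.5, abs=1e-12)


def test_ntcp_xerostomia_matches_high_precision_oracle():
    d = (30.0, 25.0, 16.0)
    s = (sympy.Float(-2.2951, 30) + sympy.Float(0.0182, 30) * d[0]
         + sympy.Float(0.0996, 30) * (sympy.sqrt(sympy.Float(d[1], 30))
                                      + sympy.sqrt(sympy.Float(d[2], 30))))
    assert M.ntcp_xerostomia(*d) == pytest.approx(_sympy_logistic(s),
                                                  abs=1e-12)


def test_ntcp_dysphagia_zero_dose_and_site_term():
    expected = _sympy_logistic(sympy.Rational(-40536, 10000))
    assert M.ntcp_dysphagia(0, 0, 0, 0, pharynx=False) == pytest.approx(
        expected, abs=1e-12)
    # the pharynx site coefficient is negative: the flag lowers NTCP
    assert (M.ntcp_dysphagia(30, 40, 30, 30, pharynx=True)
            < M.ntcp_dysphagia(30, 40, 30, 30, pharynx=False))


def test_ntcp_dysphagia_matches_high_precision_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        d = rng.uniform(0, 70, 4)
        s = (sympy.Float(-4.0536, 30) + sympy.Float(0.03, 30) * d[0]
             + sympy.Float(0.0236, 30) * d[1]
             + sympy.Float(0.0095, 30) * d[2]
             + sympy.Float(0.0133, 30) * d[3]
             - sympy.Float(0.6281, 30))
        assert M.ntcp_dysphagia(*d, pharynx=True) == pytest.approx(
            _sympy_logistic(s), abs=1e-12)


def test_ntcp_monotone_increasing_in_every_dose():
    base = M.ntcp_xerostomia(20, 20, 20)
    assert M.ntcp_xerostomia(25, 20, 20) > base
    assert M.ntcp_xerostomia(20, 25, 20) > base
    assert M.ntcp_xerostomia(20, 20, 25) > base
    base_d = M.ntcp_dysphagia(20, 20, 20, 20)
    for i in range(4):
        d = [20.0] * 4
        d[i] = 30.0
        assert M.ntcp_dysphagia(*d) > base_d
    with pytest.raises(ValueError):
        M.ntcp_xerostomia(-1, 0, 0)


# -- gamma -----------------------------------------------------------------

def test_gamma_identity_is_100(grid):
    rng = np.random.default_rng(4)
    dose = rng.uniform(10, 70, grid.shape)
    assert M.gamma_pass_rate(dose, dose, grid) == 100.0


def test_gamma_passes_one_criterion_shift():
    g = GridSpec((24, 24, 8), (2.0, 2.0, 2.0))
    x = np.arange(24) * 2.0
    ref = np.tile((50 + 0.8 * x)[:, None, None], (1, 24, 8))
    # shift by exactly 2 mm (one voxel) = one DTA width -> gamma <= 1
    ev = np.roll(ref, 1, axis=0)
    ev[0] = ref[0]
    assert M.gamma_pass_rate(ref, ev, g, dta_mm=2.0, dd_frac=0.02) == 100.0


def test_gamma_matches_exhaustive_search_oracle():
    g = GridSpec((16, 16, 16), (3.0, 3.0, 3.0))
    rng = np.random.default_rng(5)
    base = rng.uniform(20, 70, g.shape)
    from scipy import ndimage
    ref = ndimage.gaussian_filter(base, 2.0)
    ev = ref + rng.normal(0, 0.8, g.shape)
    rate = M.gamma_pass_rate(ref, ev, g, dta_mm=2.0, dd_frac=0.02)

    # brute-force: all voxel offsets within 3*dta, straight loops
    ref_max = ref.max()
    include = np.argwhere(ref >= 0.1 * ref_max)
    offs = [(i, j, k) for i in (-2, -1, 0, 1, 2) for j in (-2, -1, 0, 1, 2)
            for k in (-2, -1, 0, 1, 2)
            if (9 * (i * i + j * j + k * k)) <= 36.0]
    npass = 0
    for (i, j, k) in include:
        best = np.inf
        for (di, dj, dk) in offs:
            ii = min(max(i + di, 0), 15)
            jj = min(max(j + dj, 0), 15)
            kk = min(max(k + dk, 0), 15)
            dist2 = 9 * (di * di + dj * dj + dk * dk) / 4.0
            dd2 = ((ev[ii, jj, kk] - ref[i, j, k]) / (0.02 * ref_max)) ** 2
            best = min(best, dist2 + dd2)
        npass += best <= 1.0 + 1e-9
    assert rate == pytest.approx(100.0 * npass / len(include))


# -- Wilcoxon --------------------------------------------------------------

def test_wilcoxon_identical_samples_degenerate():
    with pytest.warns(UserWarning):
        p = M.wilcoxon_paired([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert p == 1.0


def test_wilcoxon_all_positive_n10_exact():
    a = np.arange(10) + 10.0
    b = np.arange(10).astype(float)
    assert M.wilcoxon_paired(a, b) == pytest.approx(2 / 2 ** 10, rel=1e-12)


def test_wilcoxon_symmetric_differences_near_one():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = a + np.array([0.5, -0.5, 1.5, -1.5, 2.5, -2.5])
    assert M.wilcoxon_paired(a, b) > 0.5


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_wilcoxon_matches_full_enumeration(seed):
    """Exact p equals brute-force enumeration of all 2^n sign assignments."""
    rng = np.random.default_rng(seed)
    n = 9
    a = rng.normal(0, 1, n)
    b = a + rng.normal(0.4, 1, n)
    diff = a - b
    diff = diff[diff != 0]
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=len(diff)):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats)
    lo = (stats <= w_obs + 1e-9).mean()
    hi = (stats >= w_obs - 1e-9).mean()
    expected = min(1.0, 2 * min(lo, hi))
    assert M.wilcoxon_paired(a, b) == pytest.approx(expected, rel=1e-12)


def test_wilcoxon_agrees_with_scipy_exact():
    from scipy import stats as ss
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 12)
    b = a + rng.normal(0.5, 1, 12)
    ours = M.wilcoxon_paired(a, b)
    ref = ss.wilcoxon(a, b, mode="exact").pvalue
    assert ours == pytest.approx(ref, rel=1e-9)


def test_wilcoxon_input_validation():
    with pytest.raises(ValueError):
        M.wilcoxon_paired([1, 2], [1, 2])
    with pytest.raises(ValueError):
        M.wilcoxon_paired([1, 2, 3, 4, 5], [1, 2, 3])


# -- goals -----------------------------------------------------------------

def _full_metrics(overrides=None):
    vals = {
        ("ctv_high", "voxmin", "v94"): 99.0,
        ("ctv_low", "voxmin", "v94"): 99.0,
        ("ctv_high", "voxmax", "d2"): 75.0,
        ("ctv_low", "voxmax", "d2"): 70.0,
        ("brainstem", "voxmax", "d003cc"): 60.0,
        ("brainstem", "nominal", "d003cc"): 58.0,
        ("spinal_cord", "voxmax", "d003cc"): 50.0,
        ("spinal_cord", "nominal", "d003cc"): 48.0,
        ("optic", "voxmax", "d003cc"): 55.0,
        ("optic", "nominal", "d003cc"): 52.0,
    }
    vals.update(overrides or {})
    return vals


def test_goal_check_all_pass_at_boundaries():
    report = M.goal_check(_full_metrics({
        ("ctv_high", "voxmin", "v94"): 98.0 + 1e-6,
        ("brainstem", "voxmax", "d003cc"): 68.0 - 1e-6}))
    assert report.all_passed
    assert not report.replan


def test_goal_check_brainstem_overdose_named():
    report = M.goal_check(_full_metrics({
        ("brainstem", "voxmax", "d003cc"): 68.5}))
    assert not report.all_passed
    assert any("brainstem" in name and "68" in name
               for name in report.failed())


def test_goal_check_replan_trigger():
    report = M.goal_check(_full_metrics({
        ("ctv_high", "voxmin", "v94"): 93.9}), accumulated=True)
    assert report.replan
    report2 = M.goal_check(_full_metrics({
        ("ctv_high", "voxmin", "v94"): 94.1}), accumulated=True)
    assert not report2.replan


def test_goal_check_missing_structure_named():
    vals = _full_metrics()
    del vals[("spinal_cord", "voxmax", "d003cc")]
    with pytest.raises(KeyError, match="spinal_cord"):
        M.goal_check(vals)


# -- property-based invariants ---------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

_doses = st.lists(st.floats(0.0, 80.0), min_size=12, max_size=40)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(_doses, st.floats(0.0, 80.0), st.floats(0.0, 80.0))
def test_vd_nonincreasing_in_level(values, l1, l2):
    vals = np.asarray(values)
    lo, hi = sorted((l1, l2))
    assert M.vd_values(vals, lo) >= M.vd_values(vals, hi)
    assert M.vd_values(vals, 0.0) == 100.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(_doses, st.floats(0.01, 0.3), st.floats(0.01, 0.3))
def test_dcc_nonincreasing_in_volume(values, v1, v2):
    vals = np.asarray(values)
    vv = 0.027
    lo, hi = sorted((v1, v2))
    assert (M.d_cc_values(vals, vv, lo)
            >= M.d_cc_values(vals, vv, hi) - 1e-12)
    assert M.d_cc_values(vals, vv, lo) <= vals.max() + 1e-12


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(0, 70), st.floats(0, 70), st.floats(0, 70))
def test_ntcp_bounds_property(d1, d2, d3):
    p = M.ntcp_xerostomia(d1, d2, d3)
    assert 0.0 < p < 1.0
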