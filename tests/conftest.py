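import numpy as np
import pytest

from anatrobust.grids import GridSpec, StructureSet, VoxelGrid
from anatrobust.phantom_cohort import ProgressionParams, make_patient

#: coarse frame that still contains the whole phantom anatomy
SMALL_GRID = GridSpec((44, 44, 36), (4.0, 4.0, 4.0))

#: all-zero progression (weekly anatomy identical to planning)
ZERO_PARAMS = dict(
    ctv_high_loss_per_day=0.0, ctv_node_loss_per_day=0.0,
    ctv_elective_loss_per_day=0.0, ctv_high_shift_mm=0.0,
    ctv_node_shift_mm=0.0, ctv_elective_shift_mm=0.0,
    parotid_total_loss=0.0, parotid_medial_shift=0.0,
    submandibular_total_loss=0.0, submandibular_medial_shift=0.0,
    thyroid_total_loss=0.0, neck_contraction=0.0, snrv_sigma=0.0,
)


def zero_params(**overrides) -> ProgressionParams:
    kw = dict(ZERO_PARAMS)
    kw.update(overrides)
    return ProgressionParams(**kw)


@pytest.fixture(scope="session")
def small_static_patient():
    return make_patient(zero_params(), SMALL_GRID)


@pytest.fixture(scope="session")
def small_patient():
    """One progressing patient on the coarse frame."""
    return make_patient(ProgressionParams(seed=11), SMALL_GRID)


@pytest.fixture(scope="session")
def water_box():
    """Uniform water phantom for dose-engine contracts."""
    g = GridSpec((40, 40, 30), (3.0, 3.0, 3.0))
    return VoxelGrid(np.ones(g.shape), g)


@pytest.fixture()
def sphere_structures(water_box):
    g = water_box.grid
    cx, cy, cz = g.coordinate_grids()
    c = g.origin_arr + g.extent_mm / 2.0
    target = ((cx - c[0]) ** 2 + (cy - c[1]) ** 2 + (cz - c[2]) ** 2) <= 15 ** 2
    oar = (((cx - c[0] - 27) ** 2 + (cy - c[1]) ** 2
            + (cz - c[2]) ** 2) <= 9 ** 2)
    return StructureSet({"target": target, "oar": oar}, g)
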