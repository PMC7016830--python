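import numpy as np
import pytest

from rbetrans import (
    DVH,
    DoseGrid,
    StructureMask,
    fit_quadratic_xy,
    generate_cohort,
)

# The four published (D_LEM|v, D_MKM|v) translation anchor pairs.
ANCHOR_LEM = np.array([42.9, 57.7, 68.2, 72.0])
ANCHOR_MKM = np.array([28.8, 46.4, 60.0, 66.0])

# Printed five-patient compliance table: per patient, rectum volume and
# (D_20%, D_10%, D_5%, D_1%) in each RBE language.
TABLE1 = {
    "Prostate 1": {
        "group": "prostate",
        "volume_cc": 68.6,
        "lem": (26.3, 50.9, 61.4, 67.1),
        "mkm": (14.0, 38.1, 50.7, 63.3),
    },
    "Prostate 2": {
        "group": "prostate",
        "volume_cc": 58.3,
        "lem": (37.2, 54.8, 61.1, 64.5),
        "mkm": (23.6, 41.8, 49.3, 55.0),
    },
    "L_SAC 1": {
        "group": "l_sac",
        "volume_cc": 146.2,
        "lem": (47.2, 59.9, 63.8, 67.9),
        "mkm": (35.1, 50.8, 56.3, 62.7),
    },
    "L_SAC 2": {
        "group": "l_sac",
        "volume_cc": 53.5,
        "lem": (25.6, 47.7, 59.8, 67.2),
        "mkm": (11.7, 32.7, 49.7, 60.5),
    },
    "H_SAC 1": {
        "group": "h_sac",
        "volume_cc": 86.0,
        "lem": (48.6, 58.8, 63.3, 67.7),
        "mkm": (37.0, 49.4, 54.8, 60.5),
    },
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture(scope="session")
def four_pair_fit():
    return fit_quadratic_xy(ANCHOR_LEM, ANCHOR_MKM)


@pytest.fixture
def linear_dvh():
    """Exact linear survival curve: fraction (100 - d)/100 on [0, 100]."""
    edges = np.linspace(0.0, 100.0, 1001)
    return DVH(
        dose_edges=edges,
        cum_volume_fraction=1.0 - edges / 100.0,
        total_volume_cc=80.0,
        rbe_model="MKM",
    )


@pytest.fixture
def uniform_grid():
    values = np.full((4, 4, 4), 50.0)
    grid = DoseGrid(values=values, voxel_size=(2.0, 2.0, 2.0), rbe_model="MKM")
    mask = StructureMask(mask=np.ones((4, 4, 4), dtype=bool), name="rectum")
    return grid, mask


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(seed=20260904)
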