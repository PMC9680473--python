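import numpy as np
import pytest

from ivimdce.cohort import CohortConfig, LesionTruth
from ivimdce.diffusion import BScheme
from ivimdce.tofts import TimeGrid, parker_aif


@pytest.fixture
def rng():
    return np.random.default_rng(20221031)


@pytest.fixture(scope="session")
def scheme():
    return BScheme()


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()


@pytest.fixture(scope="session")
def cp(grid):
    return parker_aif(grid)


@pytest.fixture(scope="session")
def malignant_truth():
    """A lesion at the malignant-group central values of the reference
    population (D 1.07e-3 mm^2/s, D* 15.20e-3, f 13.7%, kep 1.80/min)."""
    return LesionTruth(
        lesion_id="ref", group="malignant",
        D=1.07e-3, Dstar=15.20e-3, f=0.137,
        Ktrans=0.9, kep=1.80, vp=0.02,
    )


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast end-to-end runs."""
    return CohortConfig(n_benign=6, n_malignant=14, n_voxels=12, seed=77)
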