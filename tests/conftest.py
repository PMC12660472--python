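import numpy as np
import pytest

from mednf.design import AcquisitionParams, make_block_design
from mednf.synthetic import GroundTruth, simulate_roi_run


@pytest.fixture(scope="session")
def acquisition():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_design(acquisition):
    return make_block_design(acquisition)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_run(acquisition, default_design):
    """One moderately noisy run with a -0.5% meditation deactivation."""
    truth = GroundTruth(target_deactivation_pct=-0.5, seed=42)
    return simulate_roi_run(default_design, acquisition, truth,
                            n_target_voxels=24, n_confound_voxels=24)
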