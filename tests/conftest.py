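import numpy as np
import pytest

import occupet as op


@pytest.fixture(scope="session")
def protocol():
    """The 30-frame, 90-min acquisition schedule."""
    return op.load_frame_schedule(op.DEFAULT_FRAMING)


@pytest.fixture(scope="session")
def fine_grid(protocol):
    return np.arange(0, int(protocol.total_duration) + 1, dtype=float)


@pytest.fixture(scope="session")
def reference_curve(fine_grid):
    return op.simulate_reference_curve(fine_grid)


@pytest.fixture(scope="session")
def noiseless_study():
    """8-ROI noiseless baseline/blocking pair with ledger (seed 3)."""
    return op.simulate_study(n_rois=8, noise_cv=0.0, seed=3)


@pytest.fixture(scope="session")
def fixture_rows():
    return op.load_table1_fixture()
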