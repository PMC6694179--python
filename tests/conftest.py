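import numpy as np
import pandas as pd
import pytest

import rootbranch as rb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """A coarse 6x6x6 calibration table, adequate for interpolation tests."""
    return rb.build_calibration(
        rb.default_grid_spec(6), 8_000, np.random.default_rng(777), seed=777
    )


@pytest.fixture(scope="session")
def shipped_table():
    return rb.load_default_table()


def make_sample(ibd, diameters=None, sample_id="test"):
    """Wrap an IBD vector (and optional per-record diameters) as an IBDSample."""
    ibd = np.asarray(ibd, dtype=float)
    if diameters is None:
        diameters = np.full(ibd.size, 0.5)
    else:
        diameters = np.broadcast_to(np.asarray(diameters, float), ibd.shape).copy()
    return rb.IBDSample(
        sample_id=sample_id,
        records=pd.DataFrame(
            {
                "parent_root_id": [f"r{i % 10}" for i in range(ibd.size)],
                "parent_diameter_mm": diameters,
                "ibd_mm": ibd,
            }
        ),
    )


@pytest.fixture
def sample_factory():
    return make_sample
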