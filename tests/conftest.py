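import numpy as np
import pandas as pd
import pytest

from reachbias.geometry import DEFAULT_LAYOUT


@pytest.fixture(scope="session")
def layout():
    return DEFAULT_LAYOUT


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trajectory(points, dt_ms=1000.0 / 60.0):
    """Build a trajectory DataFrame from (x, y) samples on a regular grid."""
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {
            "t_ms": np.arange(len(pts)) * dt_ms,
            "x_cm": pts[:, 0],
            "y_cm": pts[:, 1],
        }
    )
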