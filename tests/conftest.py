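import numpy as np
import pytest

from odnptraj.correlate import AcfResult
from odnptraj.trajectory import Trajectory


@pytest.fixture
def small_traj() -> Trajectory:
    rng = np.random.default_rng(11)
    t = np.arange(256, dtype=float)
    return Trajectory.from_arrays(
        t,
        {"C2": rng.standard_normal(256), "C3": rng.standard_normal(256)},
        units={"C2": "au", "C3": "au"},
    )


def make_acf(g: np.ndarray, dt: float = 1.0, variance: float = 1.0,
             channel: str = "") -> AcfResult:
    """Wrap a closed-form ACF into the result container used downstream."""
    g = np.asarray(g, float)
    return AcfResult(
        lags=np.arange(g.size, dtype=float) * dt,
        g=g,
        variance=variance,
        n_points_used=g.size,
        centering="mean",
        channel=channel,
        dt=dt,
    )
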