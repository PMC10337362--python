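import numpy as np
import pytest

from tmtrace import simulate_cohort
from tmtrace.core import Trajectory


def make_traj(x, y, pressure, t, subject_id="s1", part="A", block=2) -> Trajectory:
    return Trajectory(
        subject_id=subject_id, part=part, block=block,
        x=np.asarray(x, float), y=np.asarray(y, float),
        pressure=np.asarray(pressure, float), t=np.asarray(t, float),
    )


def line_traj(n=50, dt=0.02, speed=500.0, offset=(0.0, 0.0), pressure=1000.0,
              subject_id="s1", part="A", block=2) -> Trajectory:
    """Constant-velocity pen-down straight line, uniform sampling."""
    t = dt * np.arange(n)
    return make_traj(
        offset[0] + speed * t, offset[1] + np.full(n, 100.0),
        np.full(n, pressure), t, subject_id=subject_id, part=part, block=block,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """24 simulated subjects (8 per group) with ground truth."""
    return simulate_cohort({"HC": 8, "MCI": 8, "AD": 8}, seed=11)
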