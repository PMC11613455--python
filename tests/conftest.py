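import numpy as np
import pytest

from crowdflow import BoxSpec, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_walk_traj(rng):
    """Unwrapped free random walk of 4 molecules, known step variance."""
    F, M = 2001, 4
    dt = 0.01
    d0 = 50.0
    steps = rng.standard_normal((F - 1, M, 3)) * np.sqrt(2 * d0 * dt)
    pos = np.concatenate([np.zeros((1, M, 3)), np.cumsum(steps, axis=0)])
    traj = Trajectory(times=np.arange(F) * dt, com_positions=pos,
                      box=BoxSpec(1e6), wrapped=False,
                      ground_truth={"d0": d0})
    return traj
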