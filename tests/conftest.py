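import numpy as np
import pytest

from runtumble.types import SimulationParams, Trajectory
from runtumble.model import simulate_ensemble


@pytest.fixture
def straight_track() -> Trajectory:
    """Constant-velocity straight 3D track (2 um/min along +x)."""
    times = np.arange(0, 30, 1.5)
    pos = np.zeros((len(times), 3))
    pos[:, 0] = 3.0 * np.arange(len(times))
    return Trajectory(cell_id="straight", times=times, positions=pos)


@pytest.fixture
def separated_params() -> SimulationParams:
    """Widely separated two-state regime: long straight fast runs vs
    slow isotropic tumbles (run speed ~5x observed tumble speed)."""
    return SimulationParams(
        tau_r=12.0,
        tau_t=6.0,
        v_run_mean=4.0,
        v_run_sd=0.4,
        v_tumble_mean=3.0,  # observed speed at 1.5-min sampling ~0.8
        v_tumble_sd=0.5,
        D_theta=0.01,
        sigma_eps=0.6,
        n_cells=20,
        seed=42,
    )


@pytest.fixture
def separated_ensemble(separated_params):
    return simulate_ensemble(separated_params, total_time=120.0, seed=42)
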