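import numpy as np
import pytest

from sptnano.geometry import box_layout
from sptnano.synthetic import SimulationConfig, simulate_cell
from sptnano.trajectories import Trajectory


def make_brownian_track(rng, D=0.1, dt=0.02, n=20, track_id=0, cell_id="c", start=(0.0, 0.0)):
    steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(n - 1, 2))
    xy = np.asarray(start) + np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
    return Trajectory(track_id=track_id, cell_id=cell_id, frames=np.arange(n), xy=xy)


def make_ballistic_track(speed=0.05, n=30, track_id=0, cell_id="c"):
    xy = np.column_stack([np.arange(n) * speed, np.zeros(n)])
    return Trajectory(track_id=track_id, cell_id=cell_id, frames=np.arange(n), xy=xy)


@pytest.fixture(scope="session")
def free_tracks():
    """~400 noise-free free-diffusion tracks at D = 0.1 um^2/s."""
    cfg = SimulationConfig(
        geometry=box_layout(40, 40),
        state_occupancy=(0.0, 0.0, 1.0),
        state_diffusion=(0.001, 0.01, 0.1),
        localization_sigma=0.0,
        n_molecules=700,
        seed=11,
    )
    return simulate_cell(cfg, cell_id="free").trajectories


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
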