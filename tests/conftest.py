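import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyesorb.trajio import Topology, Trajectory

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_topology() -> Topology:
    """Minimal 4-particle topology: one dye with a 3-site core plus one
    single-site reference particle."""
    return Topology(
        masses=np.array([1.0, 2.0, 3.0, 10.0]),
        charges=np.array([0.5, -0.25, 0.75, -1.0]),
        groups={
            "DYE": np.array([0, 1, 2]),
            "DYE_core": np.array([0, 1, 2]),
            "REF": np.array([3]),
        },
    )


def make_trajectory(topology: Topology, n_frames: int = 5, seed: int = 0) -> Trajectory:
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=5.0, size=(n_frames, topology.n_particles, 3))
    times = np.arange(n_frames) * 0.1
    return Trajectory(times=times, coords=coords, topology=topology)


@pytest.fixture(scope="session")
def scripted_run():
    """A full-length scripted run shared by the slower recovery tests:
    6 dyes / one 40 Å-diameter particle, 100 ns at 0.01 ns per frame."""
    from dyesorb.synthetic import (
        DimerInterval,
        Script,
        SimConfig,
        StateInterval,
        simulate_trajectory,
    )

    script = Script(
        states={
            0: [StateInterval(10.0, 41.0, "A")],
            1: [StateInterval(20.0, 24.0, "RA")],
            4: [StateInterval(63.0, 100.0, "A")],
            5: [StateInterval(5.0, 6.0, "T")],
        },
        dimers=[DimerInterval(2, 3, 36.0, 80.0, location="solute")],
    )
    cfg = SimConfig(duration=100.0, timestep=0.01, script=script, seed=3)
    traj, top, gt = simulate_trajectory(cfg)
    return cfg, traj, top, gt
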