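"""Shared fixtures: small synthetic scenes and trajectory factories."""

from __future__ import annotations

import numpy as np
import pytest

from ionatmos.core import TrajectoryEnsemble
from ionatmos.synthetic import (
    SyntheticScene,
    UniformMobility,
    helical_surface_charges,
    simulate_ion_cloud,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_static_traj(positions, box, dt=0.1, n_frames=5, groups=None):
    """Trajectory with every frame identical."""
    pos = np.asarray(positions, dtype=float)
    frames = np.repeat(pos[None], n_frames, axis=0)
    return TrajectoryEnsemble(frames, np.asarray(box, float), dt, groups or {})


def single_cylinder_scene(
    mode="rigid",
    seed=0,
    n_frames=2000,
    frame_interval=1.0,
    dielectric=20.0,
    n_na=16,
    box=(40.0, 40.0, 27.2),
    D=0.21,
    init="wells",
    jitter=1.0,
):
    """One charged cylinder at the box center with trapped counterions.

    With the default deep wells (dielectric 20) the seeded cations stay
    bound for the whole run, so rigid and flexible variants share the same
    well occupancy and differ only through the anchor jitter.
    """
    pos, q = helical_surface_charges((box[0] / 2.0, box[1] / 2.0), box[2])
    return SyntheticScene(
        box_lengths=box,
        cylinder_centers=(box[0] / 2.0, box[0] / 2.0),
        cylinder_radius=10.0,
        axis_y=box[1] / 2.0,
        surface_charge_positions=pos,
        surface_charges=q,
        ion_counts={"na": n_na},
        mobility_map=UniformMobility(D),
        flexibility_mode=mode,
        jitter_amplitude=jitter,
        jitter_tau=5.0,
        frame_interval=frame_interval,
        n_frames=n_frames,
        seed=seed,
        dielectric=dielectric,
        init_positions=init,
    )


@pytest.fixture(scope="session")
def trapped_scene_pair():
    """Rigid/flexible trapped-counterion trajectories, shared across tests."""
    trf = simulate_ion_cloud(single_cylinder_scene("flexible", seed=2, n_frames=2500))
    trr = simulate_ion_cloud(single_cylinder_scene("rigid", seed=3, n_frames=2500))
    return trf, trr
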