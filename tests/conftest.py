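import numpy as np
import pytest

from aquaflux.permeation import ChannelSpec
from aquaflux.traj_io import Atom, Frame, Topology, Trajectory


def water_topology(n):
    return Topology([
        Atom(serial=i + 1, atom_name="O", residue_name="HOH",
             residue_number=i + 1, chain_id="W", element="O",
             vdw_radius=1.52)
        for i in range(n)
    ])


def make_water_trajectory(z_paths, box=(20.0, 20.0, 40.0), dt_ns=0.1,
                          xy=None):
    """Trajectory of water oxygens following given per-water z paths.

    z_paths: array (n_waters, n_frames). xy defaults to the box center.
    """
    z_paths = np.asarray(z_paths, dtype=float)
    n_w, n_f = z_paths.shape
    top = water_topology(n_w)
    if xy is None:
        xy = (box[0] / 2.0, box[1] / 2.0)
    frames = []
    for f in range(n_f):
        coords = np.column_stack([
            np.full(n_w, xy[0]), np.full(n_w, xy[1]), z_paths[:, f]])
        frames.append(Frame(coords, box, f * dt_ns))
    return Trajectory(top, frames)


@pytest.fixture
def simple_channel():
    return ChannelSpec(z_lo=15.0, z_hi=25.0, buffer=2.0, radial_cutoff=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
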