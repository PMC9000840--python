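import numpy as np
import pytest

from crowdsolv.model import AtomRecord, Box, Frame, MoleculeClass, Trajectory


@pytest.fixture
def cubic_box() -> Box:
    return Box.cubic(4.0)


@pytest.fixture
def water_point_topology():
    """Factory for n single-site 'water' particles (one per residue)."""

    def make(n: int):
        return [AtomRecord(index=i, name="OW", residue_name="SOL",
                           residue_index=i + 1,
                           molecule_class=MoleculeClass.WATER, mass=18.015)
                for i in range(n)]

    return make


@pytest.fixture
def single_particle_trajectory(cubic_box, water_point_topology):
    """Factory: one particle following a prescribed list of x positions."""

    def make(x_positions, dt=1.0):
        topo = water_point_topology(1)
        frames = [Frame(time=i * dt, positions=np.array([[x, 0.5, 0.5]]),
                        box=cubic_box)
                  for i, x in enumerate(x_positions)]
        return Trajectory(topo, frames)

    return make
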