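import numpy as np
import pytest

from efca.synthetic import gen_fixture_set, make_probe_system
from efca.trajectory import AtomRecord, Topology, Trajectory


@pytest.fixture(scope="session")
def fixture_set():
    return gen_fixture_set(seed=0)


@pytest.fixture()
def probe_system():
    return make_probe_system()


def build_random_trajectory(rng, n_residues=3, n_frames=20, n_ions=1, with_h=True,
                            stride_ns=0.1, box=10.0):
    """A small random trajectory: a few residues with C/H atoms plus Ca ions."""
    atoms = []
    idx = 0
    for r in range(1, n_residues + 1):
        atoms.append(AtomRecord(index=idx, name="CA", element="C",
                                residue_number=r, residue_name="ALA"))
        idx += 1
        atoms.append(AtomRecord(index=idx, name="CB", element="C",
                                residue_number=r, residue_name="ALA"))
        idx += 1
        if with_h:
            atoms.append(AtomRecord(index=idx, name="HB1", element="H",
                                    residue_number=r, residue_name="ALA"))
            idx += 1
    ion_indices = []
    for j in range(n_ions):
        atoms.append(AtomRecord(index=idx, name="CA", element="CA",
                                residue_number=100 + j, residue_name="CA"))
        ion_indices.append(idx)
        idx += 1
    top = Topology(atoms, ion_indices=ion_indices)
    coords = rng.uniform(-box, box, size=(n_frames, idx, 3))
    times = np.arange(n_frames) * stride_ns
    return Trajectory(top, coords, times)
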