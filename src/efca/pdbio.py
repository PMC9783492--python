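"""Multi-model PDB input/output for trajectories.

Trajectories are exchanged as plain-text PDB files with one MODEL/ENDMDL
block per frame and Ca2+ ions as HETATM records (element ``CA``).  Parsing
and fixed-column serialization are delegated to biotite, which enforces
equal atom counts across models and reads the element columns (77-78) with
an atom-name fallback.  PDB files carry no time axis, so frame times are
synthesized as 0, stride, 2*stride, ... from the declared frame stride.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from biotite import InvalidFileError
from biotite.structure import AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .errors import TrajectoryFormatError
from .trajectory import AtomRecord, ION_ELEMENT, Topology, Trajectory


def read_multimodel_pdb(path: str | Path, stride_ns: float = 0.1,
                        metadata: dict | None = None) -> Trajectory:
    """Read a MODEL/ENDMDL PDB file into a :class:`Trajectory`.

    The topology is taken from the first model; Ca2+ HETATM records (element
    ``CA``) are registered as ions and excluded from the protein residue
    groups.  A protein C-alpha (atom name ``CA``, element ``C``) is never
    mistaken for an ion: the distinction is made on the element and HETATM
    flag, not the atom name.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # element-guess notices
            stack = pdb.get_structure(model=None)
    except (InvalidFileError, ValueError, TypeError) as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc
    if isinstance(stack, AtomArrayStack):
        coords = np.asarray(stack.coord, dtype=float)
    else:  # single model
        coords = np.asarray(stack.coord, dtype=float)[None, :, :]
    if coords.shape[0] == 0 or coords.shape[1] == 0:
        raise TrajectoryFormatError(f"{path}: no models/atoms found")

    atoms = []
    ion_indices = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]).upper()
        hetero = bool(stack.hetero[i])
        atoms.append(
            AtomRecord(
                index=i,
                name=str(stack.atom_name[i]),
                element=element,
                residue_number=int(stack.res_id[i]),
                residue_name=str(stack.res_name[i]),
                chain=str(stack.chain_id[i]) or "A",
            )
        )
        if hetero and element == ION_ELEMENT:
            ion_indices.append(i)
    topology = Topology(atoms, ion_indices=ion_indices)
    times = np.arange(coords.shape[0]) * float(stride_ns)
    meta = {"source": str(path), "stride_ns": float(stride_ns)}
    meta.update(metadata or {})
    return Trajectory(topology, coords, times, metadata=meta)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (coordinates to 1e-3 A)."""
    top = traj.topology
    n = top.n_atoms
    ion_set = set(top.ion_indices.tolist())
    stack = AtomArrayStack(traj.n_frames, n)
    stack.coord[:] = traj.coordinates
    stack.atom_name = np.array([a.name for a in top.atoms], dtype="U6")
    stack.element = np.array([a.element.upper() for a in top.atoms], dtype="U2")
    stack.res_id = np.array([a.residue_number for a in top.atoms])
    stack.res_name = np.array([a.residue_name for a in top.atoms], dtype="U5")
    stack.chain_id = np.array([a.chain for a in top.atoms], dtype="U4")
    stack.hetero = np.array([a.index in ion_set for a in top.atoms], dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
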