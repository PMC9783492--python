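"""Trajectory data model, Kabsch superposition, RMSD and RMSF.

Coordinates are in Angstrom, times in nanoseconds.  A trajectory couples a
:class:`Topology` (atom metadata, residue grouping, Ca2+ ion indices) with a
time-ordered stack of frames on a uniform stride.  RMSD series are computed
against the first frame after optimal (Kabsch) superposition, mirroring the
convention of using the first MD frame as the reference; RMSF is the
fluctuation of each residue's selected atoms about their time-mean position
within an analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, TopologyError, TrajectoryFormatError, WindowError

#: Standard atomic masses (amu) for elements that occur in these systems.
ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CA": 40.078, "K": 39.098, "CL": 35.45, "NA": 22.990,
    "MG": 24.305, "ZN": 65.38, "FE": 55.845,
}

ION_ELEMENT = "CA"  # calcium ions appear as HETATM records with element CA


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology."""

    index: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str = "A"
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            mass = ELEMENT_MASS.get(self.element.upper())
            if mass is None:
                raise TopologyError(f"no mass known for element {self.element!r} (atom {self.index})")
            object.__setattr__(self, "mass", mass)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class Topology:
    """Ordered atoms plus residue grouping and the Ca2+ ion selection.

    Protein atoms are grouped by residue number; ion atoms (Ca2+ HETATMs)
    are kept disjoint from the protein residue groups.
    """

    def __init__(self, atoms: Sequence[AtomRecord], ion_indices: Iterable[int] = ()):
        self.atoms = tuple(atoms)
        self.ion_indices = np.array(sorted(set(ion_indices)), dtype=int)
        ion_set = set(self.ion_indices.tolist())
        self.residue_atoms: dict[int, np.ndarray] = {}
        self.residue_names: dict[int, str] = {}
        groups: dict[int, list[int]] = {}
        for atom in self.atoms:
            if atom.index in ion_set:
                continue
            groups.setdefault(atom.residue_number, []).append(atom.index)
            self.residue_names.setdefault(atom.residue_number, atom.residue_name)
        for resnum, idx in groups.items():
            self.residue_atoms[resnum] = np.array(idx, dtype=int)
        self.masses = np.array([a.mass for a in self.atoms])
        self.heavy_mask = np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_numbers(self) -> list[int]:
        return sorted(self.residue_atoms)

    def heavy_atoms_of(self, residue_number: int) -> np.ndarray:
        try:
            idx = self.residue_atoms[residue_number]
        except KeyError:
            raise TopologyError(f"no residue numbered {residue_number}")
        heavy = idx[self.heavy_mask[idx]]
        if heavy.size == 0:
            raise TopologyError(f"residue {residue_number} has no heavy atoms")
        return heavy

    def same_layout(self, other: "Topology") -> bool:
        if self.n_atoms != other.n_atoms or len(self.ion_indices) != len(other.ion_indices):
            return False
        if not np.array_equal(self.ion_indices, other.ion_indices):
            return False
        return all(
            (a.name, a.element, a.residue_number, a.residue_name)
            == (b.name, b.element, b.residue_number, b.residue_name)
            for a, b in zip(self.atoms, other.atoms)
        )


@dataclass(frozen=True)
class Frame:
    """One snapshot: time (ns) and n_atoms x 3 coordinates (Angstrom)."""

    time: float
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryFormatError(f"non-finite coordinates in frame at t={self.time} ns")


class Trajectory:
    """Topology plus a uniform-stride stack of frames."""

    def __init__(self, topology: Topology, coordinates: np.ndarray, times: np.ndarray,
                 metadata: dict | None = None):
        coordinates = np.asarray(coordinates, dtype=float)
        times = np.asarray(times, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[0] == 0:
            raise TrajectoryFormatError("trajectory needs at least one frame of shape (n_atoms, 3)")
        if coordinates.shape[1] != topology.n_atoms:
            raise TrajectoryFormatError(
                f"coordinate atoms ({coordinates.shape[1]}) != topology atoms ({topology.n_atoms})"
            )
        if times.shape[0] != coordinates.shape[0]:
            raise TrajectoryFormatError("times and frames differ in length")
        if times.size > 1:
            diffs = np.diff(times)
            if np.any(diffs <= 0):
                raise TrajectoryFormatError("frame times must be strictly increasing")
            if np.ptp(diffs) > 1e-9:
                raise TrajectoryFormatError("frame stride is not uniform (tolerance 1e-9 ns)")
        if not np.all(np.isfinite(coordinates)):
            raise TrajectoryFormatError("non-finite coordinates")
        self.topology = topology
        self.coordinates = coordinates
        self.times = times
        self.metadata = dict(metadata or {})

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def stride_ns(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    @property
    def span_ns(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coordinates=self.coordinates[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def select_atoms(topology: Topology, mode: str = "heavy") -> np.ndarray:
    """Protein atom selection: ``heavy`` (default), ``ca`` (C-alpha) or ``all``.

    Ions are never part of a protein selection.
    """
    protein = np.concatenate([topology.residue_atoms[r] for r in topology.residue_numbers])
    protein = np.sort(protein)
    if mode == "all":
        return protein
    if mode == "heavy":
        return protein[topology.heavy_mask[protein]]
    if mode == "ca":
        names = np.array([topology.atoms[i].name for i in protein])
        elements = np.array([topology.atoms[i].element.upper() for i in protein])
        return protein[(names == "CA") & (elements == "C")]
    raise ValueError(f"unknown selection mode {mode!r}")


@dataclass(frozen=True)
class Superposition:
    """A rigid transform (rotation then translation) and its minimized RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     selection: np.ndarray | None = None,
                     weights: np.ndarray | None = None) -> Superposition:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    The returned transform maps mobile coordinates onto the reference frame;
    ``rmsd`` is the minimized weighted RMSD over the selection.  Reflections
    are excluded by the usual determinant sign correction, so the rotation is
    always proper (det = +1).
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if selection is not None:
        ref_sel = reference[selection]
        mob_sel = mobile[selection]
    else:
        ref_sel, mob_sel = reference, mobile
    if ref_sel.shape != mob_sel.shape:
        raise GeometryError("reference and mobile selections differ in shape")
    n = ref_sel.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 selected atoms, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()
    ref_com = w @ ref_sel
    mob_com = w @ mob_sel
    p = ref_sel - ref_com
    q = mob_sel - mob_com
    # rank of the centred reference must be >= 2 (not all collinear)
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) atom configuration")
    h = (q * w[:, None]).T @ p
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_com - rotation @ mob_com
    moved = q @ rotation.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - p) ** 2)))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


@dataclass(frozen=True)
class RMSDSeries:
    """Per-frame RMSD (Angstrom) against the first frame."""

    times: np.ndarray
    values: np.ndarray
    selection: str = "heavy"

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_ns": self.times, "rmsd_A": self.values}).to_csv(path, index=False)


def rmsd_series(traj: Trajectory, selection: str | np.ndarray = "heavy") -> RMSDSeries:
    """RMSD of every frame against frame 0 after Kabsch superposition."""
    sel, label = _resolve_selection(traj.topology, selection)
    ref = traj.coordinates[0]
    values = np.empty(traj.n_frames)
    values[0] = 0.0
    for i in range(1, traj.n_frames):
        values[i] = kabsch_superpose(ref, traj.coordinates[i], selection=sel).rmsd
    return RMSDSeries(times=traj.times.copy(), values=values, selection=label)


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Angstrom)."""

    residue_numbers: np.ndarray
    values: np.ndarray
    selection: str = "heavy"

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"residue_number": self.residue_numbers, "rmsf_A": self.values}).to_csv(
            path, index=False
        )


def rmsf_profile(traj: Trajectory, selection: str | np.ndarray = "heavy",
                 window: tuple[float, float] | None = None) -> RMSFProfile:
    """Per-residue RMSF about the per-atom time mean within a time window.

    Every frame is first superposed onto frame 0 over the selection; the
    fluctuation of residue r is the RMS of |x - x_mean| pooled over the
    residue's selected atoms and the frames inside ``window`` (inclusive
    bounds, in ns; ``None`` means the full trajectory).
    """
    sel, label = _resolve_selection(traj.topology, selection)
    if window is None:
        frame_mask = np.ones(traj.n_frames, dtype=bool)
    else:
        t0, t1 = window
        frame_mask = (traj.times >= t0 - 1e-9) & (traj.times <= t1 + 1e-9)
        if not frame_mask.any():
            raise WindowError(f"window {window} selects no frames")
    ref = traj.coordinates[0]
    fitted = np.empty((int(frame_mask.sum()), traj.topology.n_atoms, 3))
    k = 0
    for i in np.nonzero(frame_mask)[0]:
        sup = kabsch_superpose(ref, traj.coordinates[i], selection=sel)
        fitted[k] = sup.apply(traj.coordinates[i])
        k += 1
    mean = fitted.mean(axis=0)
    sq_dev = ((fitted - mean) ** 2).sum(axis=2)  # (n_frames, n_atoms)
    sel_set = set(sel.tolist())
    residue_numbers = []
    values = []
    for resnum in traj.topology.residue_numbers:
        idx = np.array([i for i in traj.topology.residue_atoms[resnum] if i in sel_set])
        if idx.size == 0:
            continue
        residue_numbers.append(resnum)
        values.append(float(np.sqrt(sq_dev[:, idx].mean())))
    return RMSFProfile(
        residue_numbers=np.array(residue_numbers), values=np.array(values), selection=label
    )


def _resolve_selection(topology: Topology, selection: str | np.ndarray) -> tuple[np.ndarray, str]:
    if isinstance(selection, str):
        return select_atoms(topology, selection), selection
    return np.asarray(selection, dtype=int), "custom"
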