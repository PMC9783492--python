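"""Synthetic inputs with known ground truth.

The trajectory generators stand in for production MD so that every
estimator in the package can be checked against a closed form or an exact
recorded count:

* an overdamped-Langevin (Brownian) ion in an isotropic harmonic well,
  whose stationary radial distance is chi-distributed with 3 degrees of
  freedom and scale sigma = sqrt(kB*T/k), giving a closed-form occupancy
  P(r <= c) for any cutoff;
* an i.i.d. two-state (bound/unbound) ion whose exact bound count is
  recorded in the trajectory metadata;
* per-residue isotropic Gaussian positional noise about a base structure,
  with expected RMSF = sigma * sqrt(3);
* deterministic TPC1-like vs TPC1b-like EF-hand fixture sequences and
  paired helix-loop-helix C-alpha pseudo-structures with two ion sites.

All generators are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import erf

from .errors import ConfigError
from .sequence import MultipleAlignment, SequenceRecord
from .trajectory import AtomRecord, Topology, Trajectory

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL_MOL_K = 0.0019872
DEFAULT_TEMPERATURE_K = 300.0

#: Euler-Maruyama accuracy guard: k*dt/gamma must stay below this.
EM_STABILITY_LIMIT = 0.1


# ---------------------------------------------------------------------------
# harmonic-well ion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicIonConfig:
    """Overdamped Langevin ion in an isotropic harmonic well.

    ``gamma`` is the friction coefficient in kcal*mol^-1*ps*A^-2 (the
    overdamped update needs only this coefficient; the stationary law
    sigma^2 = kB*T/k does not depend on it).  ``dt_ps`` is the
    Euler-Maruyama step; frames are emitted every ``frame_stride_ns``.
    """

    k: float                       # well stiffness, kcal/mol/A^2
    T: float = DEFAULT_TEMPERATURE_K
    gamma: float = 1.0             # friction coefficient, kcal*mol^-1*ps*A^-2
    dt_ps: float = 0.1
    n_frames: int = 5000
    frame_stride_ns: float = 0.1
    site_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k, self.T, self.gamma, self.dt_ps, self.frame_stride_ns) <= 0:
            raise ConfigError("k, T, gamma, dt_ps and frame_stride_ns must be positive")
        if self.n_frames < 1:
            raise ConfigError("need at least one frame")
        if self.k * self.dt_ps / self.gamma >= EM_STABILITY_LIMIT:
            raise ConfigError(
                f"dt too large: k*dt/gamma = {self.k * self.dt_ps / self.gamma:.3g} "
                f">= {EM_STABILITY_LIMIT}"
            )

    @property
    def sigma(self) -> float:
        """Stationary per-axis standard deviation sqrt(kB*T/k), A."""
        return float(np.sqrt(KB_KCAL_MOL_K * self.T / self.k))

    @property
    def relaxation_ps(self) -> float:
        """Positional relaxation time gamma/k, ps."""
        return self.gamma / self.k

    @classmethod
    def from_sigma(cls, sigma: float, **kwargs) -> "HarmonicIonConfig":
        """Build a config whose stationary per-axis sd is ``sigma`` A."""
        T = kwargs.pop("T", DEFAULT_TEMPERATURE_K)
        k = KB_KCAL_MOL_K * T / sigma ** 2
        return cls(k=k, T=T, **kwargs)


def harmonic_occupancy(sigma: float, cutoff_A: float) -> float:
    """P(r <= cutoff) for the stationary harmonic-well ion.

    r/sigma follows a chi distribution with 3 degrees of freedom, so
    P(r <= c) = erf(x/sqrt(2)) - sqrt(2/pi) * x * exp(-x^2/2), x = c/sigma.
    """
    x = cutoff_A / sigma
    return float(erf(x / np.sqrt(2.0)) - np.sqrt(2.0 / np.pi) * x * np.exp(-x * x / 2.0))


def gen_harmonic_ion(config: HarmonicIonConfig, topology: Topology,
                     base_coords: np.ndarray, ion: int | None = None) -> Trajectory:
    """Simulate the (first) ion in a harmonic well; protein atoms stay static.

    The Euler-Maruyama chain x_{n+1} = (1 - k*dt/gamma) x_n + sqrt(2*kB*T*dt/gamma) xi_n
    is run per axis (it is a linear recursion, evaluated with an IIR filter),
    a burn-in of 10 relaxation times is discarded, and every
    ``frame_stride_ns`` a frame is emitted.
    """
    if topology.ion_indices.size == 0:
        raise ConfigError("topology has no ions")
    ion_index = int(topology.ion_indices[0]) if ion is None else ion
    dt = config.dt_ps
    a = 1.0 - config.k * dt / config.gamma
    b = np.sqrt(2.0 * KB_KCAL_MOL_K * config.T * dt / config.gamma)
    steps_per_frame = max(1, int(round(config.frame_stride_ns * 1000.0 / dt)))
    burn_steps = int(np.ceil(10.0 * config.relaxation_ps / dt))
    n_steps = burn_steps + config.n_frames * steps_per_frame
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal((n_steps, 3))
    # x_n = a x_{n-1} + b xi_n, x_0 = 0 (well centre)
    x = lfilter([b], [1.0, -a], noise, axis=0)
    take = burn_steps + steps_per_frame * np.arange(1, config.n_frames + 1) - 1
    ion_pos = np.asarray(config.site_center, dtype=float) + x[take]
    coords = np.repeat(np.asarray(base_coords, dtype=float)[None, :, :], config.n_frames, axis=0)
    coords[:, ion_index, :] = ion_pos
    times = np.arange(config.n_frames) * config.frame_stride_ns
    meta = {
        "generator": "harmonic_ion",
        "sigma_A": config.sigma,
        "seed": config.seed,
        "burn_in_ps": burn_steps * dt,
        "stride_ns": config.frame_stride_ns,
    }
    return Trajectory(topology, coords, times, metadata=meta)


# ---------------------------------------------------------------------------
# two-state ion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateConfig:
    """I.i.d. per-frame bound/unbound ion placement."""

    p_bound: float
    bound_distance_A: float = 3.0
    unbound_distance_A: float = 8.0
    n_frames: int = 5000
    frame_stride_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bound <= 1.0):
            raise ConfigError("p_bound must lie in [0, 1]")
        if not (0 < self.bound_distance_A < self.unbound_distance_A):
            raise ConfigError("need 0 < bound_distance < unbound_distance")
        if self.n_frames < 1 or self.frame_stride_ns <= 0:
            raise ConfigError("invalid frame count or stride")


def gen_two_state(config: TwoStateConfig, topology: Topology, base_coords: np.ndarray,
                  target_residue: int | None = None, ion: int | None = None) -> Trajectory:
    """Place the ion at bound/unbound distance from a target residue per frame.

    The exact number of bound frames is recorded in
    ``trajectory.metadata['bound_count']`` so estimators can be checked
    against the generator's own count, not just the expectation.
    """
    if topology.ion_indices.size == 0:
        raise ConfigError("topology has no ions")
    ion_index = int(topology.ion_indices[0]) if ion is None else ion
    resnum = target_residue if target_residue is not None else topology.residue_numbers[0]
    anchor = base_coords[topology.heavy_atoms_of(resnum)[0]]
    rng = np.random.default_rng(config.seed)
    bound = rng.random(config.n_frames) < config.p_bound
    dist = np.where(bound, config.bound_distance_A, config.unbound_distance_A)
    coords = np.repeat(np.asarray(base_coords, dtype=float)[None, :, :], config.n_frames, axis=0)
    coords[:, ion_index, :] = anchor + np.outer(dist, np.array([1.0, 0.0, 0.0]))
    times = np.arange(config.n_frames) * config.frame_stride_ns
    meta = {
        "generator": "two_state",
        "p_bound": config.p_bound,
        "bound_count": int(bound.sum()),
        "target_residue": resnum,
        "seed": config.seed,
        "stride_ns": config.frame_stride_ns,
    }
    return Trajectory(topology, coords, times, metadata=meta)


# ---------------------------------------------------------------------------
# Gaussian-noise trajectories
# ---------------------------------------------------------------------------

def gen_noise_trajectory(topology: Topology, base_coords: np.ndarray,
                         sigma: float | dict[int, float], n_frames: int, seed: int = 0,
                         stride_ns: float = 0.1) -> Trajectory:
    """Isotropic Gaussian displacement of every atom about a base structure.

    ``sigma`` is either one value (A, per axis) for all residues or a mapping
    residue_number -> sigma; atoms of unlisted residues stay fixed.  Frame 0
    is the unperturbed base structure (it serves as the RMSD/RMSF reference),
    noise is applied from frame 1 on.  Expected per-residue RMSF is
    sigma * sqrt(3).
    """
    if n_frames < 1:
        raise ConfigError("need at least one frame")
    base = np.asarray(base_coords, dtype=float)
    sig = np.zeros(topology.n_atoms)
    if isinstance(sigma, dict):
        for resnum, s in sigma.items():
            sig[topology.residue_atoms[resnum]] = s
    else:
        for resnum in topology.residue_numbers:
            sig[topology.residue_atoms[resnum]] = sigma
    rng = np.random.default_rng(seed)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    if n_frames > 1:
        noise = rng.standard_normal((n_frames - 1, topology.n_atoms, 3)) * sig[None, :, None]
        coords[1:] += noise
    times = np.arange(n_frames) * stride_ns
    meta = {"generator": "noise", "seed": seed, "stride_ns": stride_ns}
    return Trajectory(topology, coords, times, metadata=meta)


def static_trajectory(topology: Topology, base_coords: np.ndarray, n_frames: int = 2,
                      stride_ns: float = 0.1) -> Trajectory:
    """A trajectory whose every frame is the base structure."""
    coords = np.repeat(np.asarray(base_coords, dtype=float)[None, :, :], n_frames, axis=0)
    times = np.arange(n_frames) * stride_ns
    return Trajectory(topology, coords, times, metadata={"generator": "static"})


# ---------------------------------------------------------------------------
# probe system and fixtures
# ---------------------------------------------------------------------------

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def make_probe_system(site_center=(0.0, 0.0, 0.0), n_ions: int = 1):
    """Minimal topology for estimator tests: one GLY C-alpha at the site
    centre (so residue-ion distance equals the ion's radial excursion) plus
    ion(s).  Returns ``(topology, base_coords)``.
    """
    center = np.asarray(site_center, dtype=float)
    atoms = [AtomRecord(index=0, name="CA", element="C", residue_number=1, residue_name="GLY")]
    coords = [center]
    for j in range(n_ions):
        atoms.append(
            AtomRecord(index=1 + j, name="CA", element="CA", residue_number=100 + j,
                       residue_name="CA")
        )
        coords.append(center + np.array([3.0 + j, 0.0, 0.0]))
    top = Topology(atoms, ion_indices=range(1, 1 + n_ions))
    return top, np.array(coords)


# Fixture sequence layout: helixE(9) loop(12) helixF(9) linker(17) helixE(9)
# loop(12) helixF(9) = 77 residues.  The TPC1b-like variant replaces the
# acidic loops with positive/hydrophobic ones and drops the last linker
# residue, which appears as a single gap at alignment column 47.
HELIX_E = "EQLKRLLEA"
HELIX_F = "LREMLQELA"
LINKER = "GSGSTKNSAGSSTGQAN"
LOOP1_TPC1 = "DKDGDGTITTKE"
LOOP2_TPC1 = "DADGNGEISAAE"
LOOP1_TPC1B = "KKLGRGTITTKA"
LOOP2_TPC1B = "RALGKGVISAAK"

TPC1_LIKE_ID = "TPC1_like"
TPC1B_LIKE_ID = "TPC1b_like"

#: Alignment columns of the two 12-residue loops.
LOOP1_COLUMNS = tuple(range(10, 22))
LOOP2_COLUMNS = tuple(range(57, 69))
#: Coordinating loop positions (1, 3, 5, 7, 9, 12) as alignment columns.
SITE_COLUMNS = {
    "EF1": (10, 12, 14, 16, 18, 21),
    "EF2": (57, 59, 61, 63, 65, 68),
}
GAP_COLUMN = 47


@dataclass(frozen=True)
class SyntheticStructure:
    """A C-alpha helix-loop-helix pseudo-structure with two ion sites."""

    topology: Topology
    coordinates: np.ndarray
    site_centers: dict


@dataclass(frozen=True)
class FixtureSet:
    """Deterministic TPC1-like vs TPC1b-like EF-hand fixtures."""

    tpc1_like: SequenceRecord
    tpc1b_like: SequenceRecord
    alignment: MultipleAlignment
    site_columns: dict
    site_positions: dict   # per sequence id: site name -> 1-based residue positions
    structures: dict       # per sequence id: SyntheticStructure


def _build_structure(sequence: str, loop1_res: tuple[int, ...], loop2_res: tuple[int, ...]):
    """Place loop residues on 4-A rings around the two ion sites and all other
    residues on a rail 7.5 A away from both, one C-alpha per residue."""
    site1 = np.array([0.0, 0.0, 0.0])
    site2 = np.array([24.0, 0.0, 0.0])
    n = len(sequence)
    coords = np.zeros((n + 2, 3))
    atoms = []
    rail_j = 0
    for i, aa in enumerate(sequence, start=1):
        if i in loop1_res or i in loop2_res:
            loop = loop1_res if i in loop1_res else loop2_res
            site = site1 if i in loop1_res else site2
            k = loop.index(i)
            theta = 2.0 * np.pi * k / len(loop)
            pos = site + np.array([0.0, 4.0 * np.cos(theta), 4.0 * np.sin(theta)])
        else:
            pos = np.array([-12.0 + 0.8 * rail_j, 7.5, 0.0])
            rail_j += 1
        coords[i - 1] = pos
        atoms.append(
            AtomRecord(index=i - 1, name="CA", element="C", residue_number=i,
                       residue_name=_AA_1TO3[aa])
        )
    for j, site in enumerate([site1, site2]):
        atoms.append(
            AtomRecord(index=n + j, name="CA", element="CA", residue_number=1000 + j,
                       residue_name="CA")
        )
        coords[n + j] = site
    top = Topology(atoms, ion_indices=(n, n + 1))
    return SyntheticStructure(
        topology=top, coordinates=coords,
        site_centers={"EF1": site1, "EF2": site2},
    )


def gen_fixture_set(seed: int = 0) -> FixtureSet:
    """Build the deterministic fixture pair (the seed is accepted for API
    uniformity; the fixtures themselves are fully deterministic)."""
    tpc1_seq = HELIX_E + LOOP1_TPC1 + HELIX_F + LINKER + HELIX_E + LOOP2_TPC1 + HELIX_F
    tpc1b_gapped = (
        HELIX_E + LOOP1_TPC1B + HELIX_F + LINKER[:-1] + "-" + HELIX_E + LOOP2_TPC1B + HELIX_F
    )
    tpc1b_seq = tpc1b_gapped.replace("-", "")
    assert len(tpc1_seq) == 77 and len(tpc1b_seq) == 76
    assert tpc1b_gapped[GAP_COLUMN - 1] == "-"

    tpc1 = SequenceRecord(id=TPC1_LIKE_ID, residues=tpc1_seq,
                          description="synthetic EF-hand domain, TPC1-like (acidic loops)")
    tpc1b = SequenceRecord(id=TPC1B_LIKE_ID, residues=tpc1b_seq,
                           description="synthetic EF-hand domain, TPC1b-like (basic loops)")
    alignment = MultipleAlignment(ids=(TPC1_LIKE_ID, TPC1B_LIKE_ID),
                                  rows=(tpc1_seq, tpc1b_gapped))

    def shift(col: int) -> int:
        return col if col < GAP_COLUMN else col - 1

    site_positions = {
        TPC1_LIKE_ID: {name: tuple(cols) for name, cols in SITE_COLUMNS.items()},
        TPC1B_LIKE_ID: {name: tuple(shift(c) for c in cols) for name, cols in SITE_COLUMNS.items()},
    }
    structures = {
        TPC1_LIKE_ID: _build_structure(
            tpc1_seq, tuple(range(10, 22)), tuple(range(57, 69))
        ),
        TPC1B_LIKE_ID: _build_structure(
            tpc1b_seq, tuple(range(10, 22)), tuple(range(56, 68))
        ),
    }
    return FixtureSet(
        tpc1_like=tpc1, tpc1b_like=tpc1b, alignment=alignment,
        site_columns={k: tuple(v) for k, v in SITE_COLUMNS.items()},
        site_positions=site_positions, structures=structures,
    )
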