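"""Point-charge surrogate for binding-site electrostatics.

A coarse, compositional stand-in for full Poisson-Boltzmann surfaces: each
charged residue contributes one integer formal charge (Asp/Glu -1, Lys/Arg
+1, His neutral) located at its charged-group centroid, and a binding site
is scored by the net formal charge inside a sphere plus the Coulomb
potential of all charges at the site centre in a uniform dielectric.  Only
ordinal comparisons between sites are meaningful at this resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SingularityError
from .trajectory import Frame, Topology

#: Coulomb constant in kcal * A / (mol * e^2).
COULOMB_K = 332.06
DEFAULT_DIELECTRIC = 4.0
MIN_CHARGE_DISTANCE_A = 0.1

#: Formal side-chain charge per 3-letter residue name (His neutral).
RESIDUE_FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}

#: Side-chain atoms whose centroid locates the charge, when present.
CHARGED_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}


@dataclass(frozen=True)
class PointChargeSet:
    """Formal point charges with their source residues."""

    positions: np.ndarray  # (n, 3) Angstrom
    charges: np.ndarray    # (n,) elementary charges
    residue_numbers: np.ndarray

    def __len__(self) -> int:
        return self.charges.size

    def subset(self, mask: np.ndarray) -> "PointChargeSet":
        return PointChargeSet(self.positions[mask], self.charges[mask], self.residue_numbers[mask])


def point_charges_from_frame(frame: Frame, topology: Topology) -> PointChargeSet:
    """Collect formal charges of all charged residues in a frame.

    The charge sits at the centroid of the residue's charged-group atoms
    (carboxylate oxygens, Lys NZ, Arg guanidinium nitrogens) when those are
    present, else at the residue's heavy-atom mass-weighted COM (the CA
    position for reduced C-alpha models).
    """
    positions, charges, resnums = [], [], []
    for resnum in topology.residue_numbers:
        resname = topology.residue_names[resnum].upper()
        q = RESIDUE_FORMAL_CHARGE.get(resname)
        if q is None:
            continue
        idx = topology.residue_atoms[resnum]
        group_names = CHARGED_GROUP_ATOMS[resname]
        group = [i for i in idx if topology.atoms[i].name in group_names]
        if group:
            pos = frame.coordinates[group].mean(axis=0)
        else:
            heavy = topology.heavy_atoms_of(resnum)
            m = topology.masses[heavy]
            pos = (frame.coordinates[heavy] * m[:, None]).sum(axis=0) / m.sum()
        positions.append(pos)
        charges.append(q)
        resnums.append(resnum)
    return PointChargeSet(
        positions=np.array(positions, dtype=float).reshape(-1, 3),
        charges=np.array(charges, dtype=float),
        residue_numbers=np.array(resnums, dtype=int),
    )


def coulomb_potential(charges: PointChargeSet, point: np.ndarray,
                      dielectric: float = DEFAULT_DIELECTRIC) -> float:
    """Coulomb potential (kcal/mol/e) at a point: sum k*q_i / (eps * r_i)."""
    if len(charges) == 0:
        return 0.0
    point = np.asarray(point, dtype=float)
    r = np.sqrt(((charges.positions - point) ** 2).sum(axis=1))
    if np.any(r <= MIN_CHARGE_DISTANCE_A):
        raise SingularityError(
            f"evaluation point within {MIN_CHARGE_DISTANCE_A} A of a charge"
        )
    return float(COULOMB_K / dielectric * (charges.charges / r).sum())


@dataclass(frozen=True)
class SiteScore:
    """Electronegativity score of a candidate Ca2+ binding site."""

    center: np.ndarray
    radius_A: float
    net_charge: int
    potential: float  # kcal/mol/e at the centre

    def as_row(self) -> dict:
        return {
            "center_x": float(self.center[0]),
            "center_y": float(self.center[1]),
            "center_z": float(self.center[2]),
            "radius_A": self.radius_A,
            "net_charge": self.net_charge,
            "potential_kcal_mol_e": self.potential,
        }


def site_electronegativity(frame: Frame, topology: Topology, site_center: np.ndarray,
                           radius_A: float, dielectric: float = DEFAULT_DIELECTRIC) -> SiteScore:
    """Score a binding site: net formal charge within the radius + potential.

    The net charge sums the formal charges of residues whose charged-group
    centroid lies within ``radius_A`` of the centre; the potential is the
    Coulomb potential at the centre from *all* charges.  An empty
    neighbourhood scores net charge 0 with the distal potential only.
    """
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    site_center = np.asarray(site_center, dtype=float)
    charges = point_charges_from_frame(frame, topology)
    if len(charges) == 0:
        return SiteScore(site_center, radius_A, 0, 0.0)
    r = np.sqrt(((charges.positions - site_center) ** 2).sum(axis=1))
    net = int(charges.charges[r <= radius_A].sum())
    pot = coulomb_potential(charges, site_center, dielectric=dielectric)
    return SiteScore(center=site_center, radius_A=radius_A, net_charge=net, potential=pot)


def site_scores_to_csv(scores: dict[str, SiteScore], path) -> None:
    rows = [{"site": name, **score.as_row()} for name, score in scores.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def grid_potential(charges: PointChargeSet, points: np.ndarray,
                   dielectric: float = DEFAULT_DIELECTRIC) -> np.ndarray:
    """Potential at many points; for plain-text XYZ+value export."""
    return np.array([coulomb_potential(charges, p, dielectric) for p in np.asarray(points)])
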