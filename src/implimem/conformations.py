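"""Idealized per-residue conformations for calibration.

Calibration needs, for every amino acid, at least one representative
conformation with per-atom exposed surface areas.  This module builds one
extended-conformation template per standard residue from ideal internal
coordinates (standard bond lengths, tetrahedral/trigonal angles, trans side
chains, exact planar rings) using the natural-extension reference frame
(NeRF) construction.  Users may instead point the database at a directory of
PDB files of their own residue conformations.

The templates are synthetic idealized geometry: bond lengths and angles are
textbook values and chi angles are all trans, which is sufficient because the
calibration constraint is imposed on whatever conformations the database
holds, not on a particular experimental rotamer ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .energy_core import Particle, ParticleSystem
from .membrane_params import STANDARD_RESIDUES

__all__ = ["ConformationDB", "build_residue_template", "nerf_place"]


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from reference atoms A-B-C with internal coordinates.

    bond = |C-D|, angle = B-C-D, dihedral = A-B-C-D (degrees).
    """
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Side-chain heavy-atom topologies: atom -> (ref1, ref2, ref3, bond A,
# angle deg, dihedral deg).  References are previously placed atom names;
# backbone N/CA/C/O and CB are placed first.  Chi angles are trans (180);
# rings traverse with dihedral 0 / +-90 branches to stay planar and close.
_SIDECHAIN_ZMAT: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "ALA": [],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
        ("NE", "CB", "CG", "CD", 1.46, 112.0, 180.0),
        ("CZ", "CG", "CD", "NE", 1.33, 124.0, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.52, 113.0, 180.0),
        ("OD1", "CA", "CB", "CG", 1.23, 121.0, 90.0),
        ("ND2", "CA", "CB", "CG", 1.33, 117.0, -90.0),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.52, 113.0, 180.0),
        ("OD1", "CA", "CB", "CG", 1.25, 119.0, 90.0),
        ("OD2", "CA", "CB", "CG", 1.25, 119.0, -90.0),
    ],
    "CYS": [("SG", "N", "CA", "CB", 1.81, 114.0, 180.0)],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 112.0, 180.0),
        ("OE1", "CB", "CG", "CD", 1.23, 121.0, 90.0),
        ("NE2", "CB", "CG", "CD", 1.33, 117.0, -90.0),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 112.0, 180.0),
        ("OE1", "CB", "CG", "CD", 1.25, 119.0, 90.0),
        ("OE2", "CB", "CG", "CD", 1.25, 119.0, -90.0),
    ],
    # glycine's "side chain" is its two alpha-hydrogens (typed Hnc), so the
    # residue still exposes calibratable side-chain surface
    "GLY": [
        ("HA2", "C", "N", "CA", 1.09, 109.5, -122.0),
        ("HA3", "C", "N", "CA", 1.09, 109.5, 118.0),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.49, 114.0, 180.0),
        ("ND1", "CA", "CB", "CG", 1.38, 122.7, 90.0),
        ("CD2", "CA", "CB", "CG", 1.35, 131.0, -90.0),
        ("CE1", "CB", "CG", "ND1", 1.32, 109.0, 180.0),
        ("NE2", "CG", "ND1", "CE1", 1.31, 108.0, 0.0),
    ],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.53, 110.4, 180.0),
        ("CG2", "N", "CA", "CB", 1.53, 110.5, -60.0),
        ("CD1", "CA", "CB", "CG1", 1.51, 113.8, 180.0),
    ],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.53, 116.3, 180.0),
        ("CD1", "CA", "CB", "CG", 1.52, 110.7, 180.0),
        ("CD2", "CA", "CB", "CG", 1.52, 110.7, 60.0),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
        ("CE", "CB", "CG", "CD", 1.52, 111.0, 180.0),
        ("NZ", "CG", "CD", "CE", 1.49, 112.0, 180.0),
    ],
    "MET": [
        ("CG", "N", "CA", "CB", 1.52, 114.0, 180.0),
        ("SD", "CA", "CB", "CG", 1.80, 112.7, 180.0),
        ("CE", "CB", "CG", "SD", 1.79, 100.2, 180.0),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.51, 114.0, 180.0),
        ("CD1", "CA", "CB", "CG", 1.39, 120.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.39, 120.0, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
    ],
    "PRO": [
        ("CG", "N", "CA", "CB", 1.49, 104.5, 30.0),
        ("CD", "CA", "CB", "CG", 1.50, 106.1, -35.0),
    ],
    "SER": [("OG", "N", "CA", "CB", 1.42, 111.1, 180.0)],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.43, 109.6, 180.0),
        ("CG2", "N", "CA", "CB", 1.52, 110.5, -60.0),
    ],
    "TRP": [
        ("CG", "N", "CA", "CB", 1.50, 114.0, 180.0),
        ("CD1", "CA", "CB", "CG", 1.37, 127.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.43, 126.6, -90.0),
        ("NE1", "CB", "CG", "CD1", 1.38, 110.1, 180.0),
        ("CE2", "CG", "CD1", "NE1", 1.37, 109.0, 0.0),
        ("CE3", "CB", "CG", "CD2", 1.40, 133.9, 180.0),
        ("CZ2", "CD1", "NE1", "CE2", 1.40, 130.1, 180.0),
        ("CZ3", "CG", "CD2", "CE3", 1.39, 118.8, 180.0),
        ("CH2", "NE1", "CE2", "CZ2", 1.37, 117.5, 180.0),
    ],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.51, 114.0, 180.0),
        ("CD1", "CA", "CB", "CG", 1.39, 120.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.39, 120.0, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.38, 120.0, 180.0),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.52, 110.5, 180.0),
        ("CG2", "N", "CA", "CB", 1.52, 110.5, -60.0),
    ],
}

_ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}


def build_residue_template(residue: str) -> ParticleSystem:
    """One heavy-atom extended conformation of a standard residue.

    Backbone N/CA/C/O plus the side chain of ideal internal coordinates; the
    returned system is all-atom representation with is_sidechain flags set
    (backbone = N, CA, C, O).
    """
    residue = residue.upper()
    if residue not in _SIDECHAIN_ZMAT:
        raise KeyError(f"not a standard residue: {residue!r}")
    coords: dict[str, np.ndarray] = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
    }
    # C in the xy-plane at the ideal N-CA-C angle of 111 deg
    theta = math.radians(180.0 - 111.0)
    coords["C"] = coords["CA"] + 1.525 * np.array([math.cos(theta), math.sin(theta), 0.0])
    coords["O"] = nerf_place(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, 180.0)
    if residue != "GLY":
        coords["CB"] = nerf_place(coords["C"], coords["N"], coords["CA"], 1.53, 110.5, -122.0)
    for name, r1, r2, r3, bond, angle, dihedral in _SIDECHAIN_ZMAT[residue]:
        coords[name] = nerf_place(coords[r1], coords[r2], coords[r3], bond, angle, dihedral)

    backbone = {"N", "CA", "C", "O"}
    particles = []
    for i, (name, pos) in enumerate(coords.items()):
        element = name[0] if name[0] in _ELEMENT_RADII else "C"
        particles.append(
            Particle(
                id=i,
                position=pos,
                radius=_ELEMENT_RADII[element],
                type_label=name,
                residue_id=("A", residue, 1),
                is_sidechain=name not in backbone,
            )
        )
    return ParticleSystem(particles, "all-atom")


@dataclass
class ConformationDB:
    """Per-residue conformations with precomputed SASA.

    By default, holds one idealized extended template per standard residue
    (typed and with SASA filled in lazily by the calibration layer).  A
    directory of PDB files named ``<RES>*.pdb`` can be loaded instead.
    """

    conformations: dict[str, list[ParticleSystem]] = field(default_factory=dict)

    @classmethod
    def ideal(cls, residues: list[str] | None = None) -> "ConformationDB":
        residues = residues or STANDARD_RESIDUES
        return cls({r: [build_residue_template(r)] for r in residues})

    @classmethod
    def from_directory(cls, path: str | Path) -> "ConformationDB":
        from .structures import load_pdb

        path = Path(path)
        db: dict[str, list[ParticleSystem]] = {}
        for pdb in sorted(path.glob("*.pdb")):
            res = pdb.stem[:3].upper()
            db.setdefault(res, []).append(load_pdb(pdb))
        if not db:
            raise ValueError(f"no PDB conformations found under {path}")
        return cls(db)

    def __getitem__(self, residue: str) -> list[ParticleSystem]:
        out = self.conformations[residue.upper()]
        if not out:
            raise ValueError(f"residue {residue} has no conformations")
        return out

    def __contains__(self, residue: str) -> bool:
        return residue.upper() in self.conformations

    def residues(self) -> list[str]:
        return list(self.conformations)
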