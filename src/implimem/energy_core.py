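"""Insertion energy model: membrane profile C(z), energy terms and gradients.

The membrane environment is the sigmoid

    C(z) = 0.5 - (1 + exp(alpha (|z| - z0)))^-1

which runs from -0.5 in the hydrophobic core (z = 0, the bilayer midplane) to
+0.5 in bulk water, crossing 0 exactly at the headgroup center z0.  A protein
is a set of typed particles i with exposed surface area S_i and a per-area
transfer energy E_tr(i); its insertion energy at a pose is

    E_int = - sum_i S_i E_tr(i) C(z_i)         (hydrophobic interaction)
    E_lip = a_lip sum_i S_i C(z_i)             (lipid perturbation)
    E_IMP = E_int + E_lip

where z_i is the *signed depth* of particle i in the membrane frame.  The
depth function is pluggable: planar analytic, analytic double membrane, or
nearest-vertex distance to a triangulated mesh — all energy, force and Monte
Carlo machinery works with any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .membrane_params import MembraneGeometry

__all__ = [
    "Particle",
    "ParticleSystem",
    "EnergyBreakdown",
    "DepthFunction",
    "planar_depth",
    "membrane_profile",
    "membrane_profile_derivative",
    "interaction_energy",
    "lipid_perturbation_energy",
    "total_energy",
    "energy_gradient",
    "predict_transfer_energy",
]

# exponent clip keeping exp() finite; the sigmoid is saturated far before this
_EXP_CAP = 500.0

BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3", "HA2", "HA3", "HN"}
)


class ConfigurationError(ValueError):
    """A particle is missing data (SASA / transfer energy) required by the model."""


@dataclass
class Particle:
    """One interaction site (atom or coarse-grained bead).

    sasa is the solvent-exposed surface area S_i (A^2); etr_per_area is the
    per-area transfer energy E_tr(i) (kcal mol-1 A-2, negative = hydrophobic).
    """

    id: int
    position: np.ndarray
    radius: float = 1.7
    sasa: float | None = None
    etr_per_area: float | None = None
    type_label: str = ""
    residue_id: tuple[str, str, int] = ("A", "UNK", 1)
    is_sidechain: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.radius <= 0:
            raise ValueError(f"particle {self.id}: radius must be > 0")
        if self.sasa is not None and self.sasa < 0:
            raise ValueError(f"particle {self.id}: sasa must be >= 0")


class ParticleSystem:
    """An ordered, contiguously-indexed collection of particles.

    representation is one of {"all-atom", "cg-bead", "one-bead"}.  Coordinate
    and per-particle arrays are exposed as numpy views for vectorized energy
    evaluation.
    """

    REPRESENTATIONS = ("all-atom", "cg-bead", "one-bead")

    def __init__(self, particles: Iterable[Particle], representation: str = "all-atom"):
        self.particles: list[Particle] = list(particles)
        if representation not in self.REPRESENTATIONS:
            raise ValueError(f"unknown representation {representation!r}")
        self.representation = representation
        ids = [p.id for p in self.particles]
        if ids != list(range(len(ids))):
            raise ValueError("particle ids must be unique and contiguous from 0")

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self) -> Iterator[Particle]:
        return iter(self.particles)

    def __getitem__(self, i: int) -> Particle:
        return self.particles[i]

    # -- array views -------------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.particles], dtype=float).reshape(-1, 3)

    @positions.setter
    def positions(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if len(xyz) != len(self.particles):
            raise ValueError("coordinate count mismatch")
        for p, x in zip(self.particles, xyz):
            p.position = x.copy()

    @property
    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.particles], dtype=float)

    def sasa_array(self) -> np.ndarray:
        out = np.empty(len(self.particles))
        for k, p in enumerate(self.particles):
            if p.sasa is None:
                raise ConfigurationError(
                    f"particle {p.id} ({p.residue_id}, {p.type_label!r}) has no SASA"
                )
            out[k] = p.sasa
        return out

    def etr_array(self) -> np.ndarray:
        out = np.empty(len(self.particles))
        for k, p in enumerate(self.particles):
            if p.etr_per_area is None:
                raise ConfigurationError(
                    f"particle {p.id} ({p.residue_id}, {p.type_label!r}) "
                    "has no transfer energy"
                )
            out[k] = p.etr_per_area
        return out

    def center_of_mass(self) -> np.ndarray:
        # geometric center: the model carries no masses
        return self.positions.mean(axis=0)

    def subset(self, indices: Sequence[int]) -> "ParticleSystem":
        parts = [
            replace(self.particles[i], id=k, position=self.particles[i].position.copy())
            for k, i in enumerate(indices)
        ]
        return ParticleSystem(parts, self.representation)

    def sidechain(self) -> "ParticleSystem":
        idx = [i for i, p in enumerate(self.particles) if p.is_sidechain]
        return self.subset(idx)

    def translated(self, shift: np.ndarray) -> "ParticleSystem":
        out = self.subset(range(len(self)))
        out.positions = self.positions + np.asarray(shift, dtype=float)
        return out

    def copy(self) -> "ParticleSystem":
        return self.subset(range(len(self)))


@dataclass(frozen=True)
class EnergyBreakdown:
    """E_IMP and its two components (kcal/mol); e_imp == e_int + e_lip."""

    e_int: float
    e_lip: float

    @property
    def e_imp(self) -> float:
        return self.e_int + self.e_lip

    def as_dict(self) -> dict[str, float]:
        return {"e_int": self.e_int, "e_lip": self.e_lip, "e_imp": self.e_imp}


#: A depth function maps particle positions (N,3) to signed depths (N,) and
#: local unit membrane normals (N,3).
DepthFunction = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


def planar_depth(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Planar membrane at z=0: depth is the z coordinate, normal is +z."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    normals = np.zeros_like(positions)
    normals[:, 2] = 1.0
    return positions[:, 2].copy(), normals


def _resolve_membrane(membrane, geom: MembraneGeometry):
    """Normalize the pluggable membrane argument.

    Accepts either a bare depth function (profile taken as C(z) from ``geom``)
    or a membrane object exposing .depth(positions) -> (z, normals),
    .profile(z), .profile_derivative(z) and .geom (e.g. a DoubleMembrane or a
    MeshMembraneField).  Returns (depth_fn, profile, dprofile, a_lip).
    """
    if membrane is None:
        membrane = planar_depth
    if hasattr(membrane, "profile") and hasattr(membrane, "depth"):
        g = getattr(membrane, "geom", geom)
        return (
            membrane.depth,
            membrane.profile,
            membrane.profile_derivative,
            g.a_lip,
        )
    if callable(membrane):
        return (
            membrane,
            lambda z: membrane_profile(z, geom),
            lambda z: membrane_profile_derivative(z, geom),
            geom.a_lip,
        )
    raise TypeError(f"not a membrane or depth function: {membrane!r}")


def membrane_profile(z, geom: MembraneGeometry = MembraneGeometry()):
    """The sigmoidal membrane profile C(z), even in z, in (-0.5, 0.5).

    C(z0) = 0 exactly; C(0) ~ -0.5 (core); C(+-inf) = +0.5 (water).
    Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    expo = np.clip(geom.alpha * (np.abs(z) - geom.z0), -_EXP_CAP, _EXP_CAP)
    out = 0.5 - 1.0 / (1.0 + np.exp(expo))
    return float(out) if out.ndim == 0 else out


def membrane_profile_derivative(z, geom: MembraneGeometry = MembraneGeometry()):
    """dC/dz = sign(z) alpha e / (1+e)^2 with e = exp(alpha(|z| - z0)).

    sign(0) = 0, so the force vanishes exactly at the midplane kink.
    """
    z = np.asarray(z, dtype=float)
    expo = np.clip(geom.alpha * (np.abs(z) - geom.z0), -_EXP_CAP, _EXP_CAP)
    e = np.exp(expo)
    out = np.sign(z) * geom.alpha * e / (1.0 + e) ** 2
    return float(out) if out.ndim == 0 else out


def interaction_energy(
    system: ParticleSystem,
    membrane=planar_depth,
    geom: MembraneGeometry = MembraneGeometry(),
) -> float:
    """E_int = -sum_i S_i E_tr(i) C(z_i), in kcal/mol."""
    if len(system) == 0:
        return 0.0
    depth_fn, profile, _, _ = _resolve_membrane(membrane, geom)
    z, _ = depth_fn(system.positions)
    c = profile(np.asarray(z, dtype=float))
    return float(-np.sum(system.sasa_array() * system.etr_array() * c))


def lipid_perturbation_energy(
    system: ParticleSystem,
    membrane=planar_depth,
    geom: MembraneGeometry = MembraneGeometry(),
) -> float:
    """E_lip = a_lip sum_i S_i C(z_i), in kcal/mol."""
    if len(system) == 0:
        return 0.0
    depth_fn, profile, _, a_lip = _resolve_membrane(membrane, geom)
    z, _ = depth_fn(system.positions)
    c = profile(np.asarray(z, dtype=float))
    return float(a_lip * np.sum(system.sasa_array() * c))


def total_energy(
    system: ParticleSystem,
    membrane=planar_depth,
    geom: MembraneGeometry = MembraneGeometry(),
) -> EnergyBreakdown:
    """E_IMP = E_int + E_lip at the current pose, with a pluggable membrane."""
    if len(system) == 0:
        return EnergyBreakdown(0.0, 0.0)
    depth_fn, profile, _, a_lip = _resolve_membrane(membrane, geom)
    z, _ = depth_fn(system.positions)
    c = profile(np.asarray(z, dtype=float))
    s = system.sasa_array()
    e_int = float(-np.sum(s * system.etr_array() * c))
    e_lip = float(a_lip * np.sum(s * c))
    return EnergyBreakdown(e_int, e_lip)


def energy_gradient(
    system: ParticleSystem,
    membrane=planar_depth,
    geom: MembraneGeometry = MembraneGeometry(),
) -> np.ndarray:
    """Per-particle forces F_i = -dE_IMP/dz_i * n_i (kcal mol-1 A-1), (N,3).

    Forces are directed along the local membrane normal; a particle deep in
    bulk water sees a vanishing force (saturated sigmoid).
    """
    depth_fn, _, dprofile, a_lip = _resolve_membrane(membrane, geom)
    z, normals = depth_fn(system.positions)
    dcdz = dprofile(np.asarray(z, dtype=float))
    s = system.sasa_array()
    dEdz = s * (-system.etr_array() + a_lip) * dcdz
    return -np.asarray(dEdz)[:, None] * np.asarray(normals, dtype=float)


def predict_transfer_energy(
    residue_conformation: ParticleSystem,
    geom: MembraneGeometry = MembraneGeometry(),
    center: bool = True,
) -> float:
    """Predicted side-chain transfer energy: E_IMP at the bilayer center.

    The side-chain particles are centered so their centroid sits at z = 0
    (the bilayer midplane) and E_IMP is evaluated over side-chain particles
    only, with the planar depth function.  This is the quantity that
    calibration drives onto a reference hydrophobicity-scale entry.

    A residue with no side-chain particles (bare glycine under heavy-atom
    typing) predicts 0 with a warning.
    """
    sc = residue_conformation.sidechain()
    if len(sc) == 0:
        import warnings

        warnings.warn("residue has no side-chain particles; transfer energy is 0")
        return 0.0
    if center:
        centroid = sc.center_of_mass()
        sc = sc.translated(np.array([0.0, 0.0, -centroid[2]]))
    return total_energy(sc, planar_depth, geom).e_imp


def water_reference_energy(
    residue_conformation: ParticleSystem,
    geom: MembraneGeometry = MembraneGeometry(),
) -> float:
    """E_IMP of the side chain in bulk water (C saturated at +0.5).

    Exposed alongside :func:`predict_transfer_energy` because the profile's
    +-0.5 range makes the bulk-water energy nonzero; the calibration target
    is defined literally on E_IMP at z=0, not on the difference.
    """
    sc = residue_conformation.sidechain()
    if len(sc) == 0:
        return 0.0
    s = sc.sasa_array()
    return float(0.5 * (-np.sum(s * sc.etr_array()) + geom.a_lip * np.sum(s)))
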