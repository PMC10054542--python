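"""Structure ingestion, atom typing, SASA and synthetic fixtures.

Supports three representation scales:

* all-atom — every atom is a particle, typed into one of seven classes
  {Csp3, Csp2, Hnc, Hc, O, N, S} (Csp3 single-bonded carbon, Csp2
  double-bonded/aromatic carbon, Hnc hydrogen on carbon, Hc hydrogen on
  N/O/S) via a per-residue atom-name lookup;
* cg-bead — coarse-grained beads whose composition, type, surface area and
  transfer energy come from a user correspondence table;
* one-bead — one site per residue at the side-chain centroid (CA for
  glycine).

Solvent-accessible surface areas are computed with a deterministic
Shrake-Rupley scheme (fixed golden-spiral point set, probe 1.4 A,
960 points/atom by default), so calibrations are exactly reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .energy_core import BACKBONE_ATOMS, Particle, ParticleSystem
from .membrane_params import STANDARD_RESIDUES, convert_energy

logger = logging.getLogger(__name__)

__all__ = [
    "ATOM_TYPES",
    "AtomTypeParams",
    "CorrespondenceTable",
    "load_pdb",
    "save_pdb",
    "assign_atom_types",
    "compute_sasa",
    "map_coarse_grained",
    "one_bead_correspondence",
    "make_fixture",
]

ATOM_TYPES = ("Csp3", "Csp2", "Hnc", "Hc", "O", "N", "S")

ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}
DEFAULT_PROBE = 1.4
DEFAULT_SASA_POINTS = 960

# Side-chain carbons that are sp2 (double-bonded / aromatic); all other
# carbons are sp3.  The backbone carbonyl C is sp2 in every residue.
_SP2_CARBONS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"CZ"}),
    "ASN": frozenset({"CG"}),
    "ASP": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "GLU": frozenset({"CD"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
}

# Hydrogens bonded to N/O/S (-> Hc); every other hydrogen is on carbon (-> Hnc).
_POLAR_HYDROGENS: dict[str, frozenset[str]] = {
    "*": frozenset({"H", "H1", "H2", "H3", "HN"}),     # backbone amide H
    "ARG": frozenset({"HE", "HH11", "HH12", "HH21", "HH22"}),
    "ASN": frozenset({"HD21", "HD22"}),
    "CYS": frozenset({"HG"}),
    "GLN": frozenset({"HE21", "HE22"}),
    "HIS": frozenset({"HD1", "HE2"}),
    "LYS": frozenset({"HZ1", "HZ2", "HZ3"}),
    "SER": frozenset({"HG"}),
    "THR": frozenset({"HG1"}),
    "TRP": frozenset({"HE1"}),
    "TYR": frozenset({"HH"}),
}


class TypingError(KeyError):
    """An atom could not be resolved to one of the seven type classes."""


def atom_type_of(residue: str, atom: str) -> str:
    """Map (residue, atom name) to one of the seven atom-type labels."""
    residue, atom = residue.upper(), atom.upper()
    el = atom[0] if atom[0] != "1" else atom[1]   # e.g. 1HB2-style names
    if el == "H" or (atom[0].isdigit() and "H" in atom):
        polar = _POLAR_HYDROGENS.get(residue, frozenset()) | _POLAR_HYDROGENS["*"]
        return "Hc" if atom.lstrip("123") in polar or atom in polar else "Hnc"
    if el == "C":
        if atom == "C" or atom in _SP2_CARBONS.get(residue, frozenset()):
            return "Csp2"
        return "Csp3"
    if el in ("O", "N", "S"):
        return el
    raise TypingError(f"cannot type atom {atom!r} of residue {residue!r}")


@dataclass
class AtomTypeParams:
    """Per-(residue, type) transfer energies per area (kcal mol-1 A-2).

    Entries keyed by residue name may shadow universal entries keyed "*":
    calibration is per-residue, so the same type label can carry different
    energies in different residues.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def etr(self, residue: str, type_label: str) -> float:
        key = (residue.upper(), type_label)
        if key in self.entries:
            return self.entries[key]
        wild = ("*", type_label)
        if wild in self.entries:
            return self.entries[wild]
        raise TypingError(f"no transfer energy for ({residue}, {type_label})")

    def set(self, residue: str, type_label: str, value: float) -> None:
        self.entries[(residue.upper(), type_label)] = float(value)

    def residue_slice(self, residue: str, types: list[str]) -> dict[str, float]:
        return {t: self.etr(residue, t) for t in types}

    def copy(self) -> "AtomTypeParams":
        return AtomTypeParams(dict(self.entries))

    # -- delimited text I/O: lines "residue type etr_per_area" -------------
    @classmethod
    def load(cls, path: str | Path) -> "AtomTypeParams":
        entries: dict[tuple[str, str], float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            res, typ, val = line.split()[:3]
            entries[(res.upper(), typ)] = float(val)
        if not entries:
            raise ValueError(f"no parameter entries in {path}")
        return cls(entries)

    def save(self, path: str | Path) -> None:
        lines = ["# residue type etr_per_area(kcal/mol/A2)"]
        lines += [f"{r}\t{t}\t{v:.8g}" for (r, t), v in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def default_atom_params() -> AtomTypeParams:
    """A generic universal starting parameter set (kcal mol-1 A-2).

    Apolar types carry negative (membrane-favoring) per-area energies, polar
    types positive ones.  These are neutral initial values meant to be
    calibrated against a reference scale, not a published force field.
    """
    return AtomTypeParams(
        {
            ("*", "Csp3"): -0.012,
            ("*", "Csp2"): -0.010,
            ("*", "Hnc"): -0.008,
            ("*", "Hc"): 0.012,
            ("*", "O"): 0.016,
            ("*", "N"): 0.014,
            ("*", "S"): -0.010,
        }
    )


def assign_atom_types(system: ParticleSystem, table: AtomTypeParams) -> ParticleSystem:
    """Type every atom and attach its per-area transfer energy (in place).

    The particle's type_label must hold the PDB atom name on input; on output
    it holds the resolved type class, and etr_per_area is filled from the
    table.  Raises TypingError naming residue and atom on failure.
    """
    for p in system:
        _, resname, _ = p.residue_id
        atom_name = p.type_label
        try:
            t = atom_type_of(resname, atom_name)
            p.etr_per_area = table.etr(resname, t)
        except TypingError as exc:
            raise TypingError(f"residue {resname}, atom {atom_name}: {exc}") from None
        p.type_label = t
    return system


# ---------------------------------------------------------------------------
# PDB I/O (Biopython behind the module surface)


def load_pdb(path: str | Path, include_hetero: bool = False) -> ParticleSystem:
    """Read a PDB file into a ParticleSystem (first model only).

    Alternate locations resolve to the highest-occupancy copy; waters and
    hetero records are skipped by default.  Radii are element-based; a file
    holding exactly one atom per residue is classified as one-bead.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no ATOM records usable in {path}")
    if len(models) > 1:
        logger.info("%s: %d models; using model 1", path.name, len(models))
    particles: list[Particle] = []
    counts_per_residue: list[int] = []
    for chain in models[0]:
        for residue in chain:
            hetflag = residue.id[0].strip()
            if hetflag and not include_hetero:
                continue
            if residue.get_resname() == "HOH":
                continue
            n_in_res = 0
            for atom in residue:
                if atom.is_disordered():
                    atom = max(
                        atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0
                    )
                element = (atom.element or atom.get_name()[0]).upper()
                radius = ELEMENT_RADII.get(element, 1.7)
                name = atom.get_name().upper()
                particles.append(
                    Particle(
                        id=len(particles),
                        position=np.asarray(atom.get_coord(), dtype=float),
                        radius=radius,
                        type_label=name,
                        residue_id=(chain.id, residue.get_resname(), residue.id[1]),
                        is_sidechain=name not in BACKBONE_ATOMS,
                    )
                )
                n_in_res += 1
            if n_in_res:
                counts_per_residue.append(n_in_res)
    if not particles:
        raise ValueError(f"no ATOM records usable in {path}")
    representation = (
        "one-bead" if counts_per_residue and max(counts_per_residue) == 1 else "all-atom"
    )
    return ParticleSystem(particles, representation)


def save_pdb(system: ParticleSystem, path: str | Path) -> None:
    """Write the system as a minimal PDB (ATOM records, occupancy 1.00)."""
    lines = []
    for p in system:
        chain, resname, resnum = p.residue_id
        name = (p.type_label[:4] if p.type_label else "X").upper()
        element = name[0] if name[0] in ELEMENT_RADII else "C"
        # short atom names start in column 14 by convention
        field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = p.position
        lines.append(
            f"ATOM  {p.id + 1:5d} {field:<4s} {resname[:3]:<3s} {chain[:1]}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SASA: deterministic Shrake-Rupley


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, nearly uniform points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = (1 + math.sqrt(5)) / 2
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * math.pi * k / phi
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def compute_sasa(
    system: ParticleSystem,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> ParticleSystem:
    """Fill per-particle solvent-accessible surface areas (A^2), in place.

    Shrake-Rupley: each atom's expanded sphere (r_i + probe) is sampled with
    a fixed golden-spiral point set; points falling inside any neighbor's
    expanded sphere are occluded.  Deterministic for fixed n_points.
    """
    if len(system) == 0:
        raise ValueError("cannot compute SASA of an empty system")
    pts = _golden_spiral(n_points)
    xyz = system.positions
    radii = system.radii + probe_radius
    tree = cKDTree(xyz)
    max_r = radii.max()
    for i, p in enumerate(system):
        ri = radii[i]
        sphere = xyz[i] + ri * pts
        neighbors = [
            j for j in tree.query_ball_point(xyz[i], ri + max_r) if j != i
            and np.linalg.norm(xyz[j] - xyz[i]) < ri + radii[j]
        ]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((sphere - xyz[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        p.sasa = float(4.0 * math.pi * ri**2 * exposed.mean())
    return system


# ---------------------------------------------------------------------------
# correspondence tables and coarse-graining


@dataclass
class CorrespondenceTable:
    """Rows linking (residue, bead name) to type, area, energy and makeup.

    File format (whitespace-delimited, '#' comments), one row per bead:

        residue  particle  type  area  energy  units  [atoms]

    area is a number (A^2) or the word "computed" (area taken from the bead
    sphere after mapping); atoms is a comma-separated list of constituent
    atom names, or "sidechain" / "all" (default "sidechain").
    """

    rows: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add(
        self,
        residue: str,
        particle: str,
        type_label: str,
        area: float | str,
        energy: float,
        units: str = "kcal/mol",
        atoms: str = "sidechain",
    ) -> None:
        key = (residue.upper(), particle.upper())
        if key in self.rows:
            raise ValueError(f"duplicate correspondence row {key}")
        self.rows[key] = {
            "type": type_label,
            "area": area,
            "energy": float(energy),
            "units": units,
            "atoms": atoms,
        }

    def beads_for(self, residue: str) -> list[tuple[str, dict]]:
        residue = residue.upper()
        return [(p, row) for (r, p), row in self.rows.items() if r == residue]

    def covers(self, residue: str) -> bool:
        return bool(self.beads_for(residue))

    @classmethod
    def load(cls, path: str | Path) -> "CorrespondenceTable":
        table = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("residue"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"malformed correspondence row: {raw!r}")
            res, bead, typ, area, energy, units = parts[:6]
            atoms = parts[6] if len(parts) > 6 else "sidechain"
            area_val: float | str = area if area == "computed" else float(area)
            table.add(res, bead, typ, area_val, float(energy), units, atoms)
        if not table.rows:
            raise ValueError(f"no correspondence rows in {path}")
        return table

    def save(self, path: str | Path) -> None:
        lines = ["# residue particle type area energy units atoms"]
        for (r, p), row in self.rows.items():
            lines.append(
                f"{r}\t{p}\t{row['type']}\t{row['area']}\t{row['energy']:.6g}"
                f"\t{row['units']}\t{row['atoms']}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def one_bead_correspondence(scale, bead_area: float = 60.0) -> CorrespondenceTable:
    """One-bead table from a hydrophobicity scale: one side-chain-centroid
    bead per residue, bead energy = the scale's transfer free energy."""
    table = CorrespondenceTable()
    for res in scale.residues():
        table.add(res, "B", res, bead_area, scale[res], scale.units, "sidechain")
    return table


DEFAULT_BEAD_RADIUS = 2.3


def map_coarse_grained(
    system: ParticleSystem, table: CorrespondenceTable
) -> ParticleSystem:
    """Map an all-atom system onto beads defined by a correspondence table.

    Beads sit at the center of geometry of their constituent atoms (for a
    one-bead table: the side-chain centroid, CA fallback for glycine).  Bead
    per-area energies are energy/area in kcal units; "computed" areas are the
    isolated-bead sphere area 4 pi (r+probe)^2.
    """
    residues: dict[tuple[str, str, int], list[Particle]] = {}
    order: list[tuple[str, str, int]] = []
    for p in system:
        if p.residue_id not in residues:
            order.append(p.residue_id)
        residues.setdefault(p.residue_id, []).append(p)

    beads: list[Particle] = []
    one_per_residue = True
    for rid in order:
        chain, resname, resnum = rid
        atoms = residues[rid]
        rows = table.beads_for(resname)
        if not rows:
            raise KeyError(f"correspondence table does not cover residue {resname}")
        if len(rows) > 1:
            one_per_residue = False
        for bead_name, row in rows:
            sel = row["atoms"]
            if sel == "all":
                members = atoms
            elif sel == "sidechain":
                members = [a for a in atoms if a.is_sidechain] or [
                    a for a in atoms if a.type_label == "CA"
                ]
            else:
                wanted = {s.strip().upper() for s in sel.split(",")}
                members = [a for a in atoms if a.type_label.upper() in wanted]
            if not members:
                raise KeyError(
                    f"no atoms for bead {bead_name} of {resname} {resnum} (selector {sel!r})"
                )
            center = np.mean([a.position for a in members], axis=0)
            area = row["area"]
            if area == "computed":
                area = 4.0 * math.pi * (DEFAULT_BEAD_RADIUS + DEFAULT_PROBE) ** 2
            energy_kcal = convert_energy(row["energy"], row["units"], "kcal/mol")
            beads.append(
                Particle(
                    id=len(beads),
                    position=center,
                    radius=DEFAULT_BEAD_RADIUS,
                    sasa=float(area),
                    etr_per_area=energy_kcal / float(area),
                    type_label=row["type"],
                    residue_id=rid,
                    is_sidechain=True,
                )
            )
    rep = "one-bead" if one_per_residue else "cg-bead"
    return ParticleSystem(beads, rep)


# ---------------------------------------------------------------------------
# synthetic fixtures

HELIX_RISE = 1.5          # A per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # A, side-chain centroid radius from the axis
FIXTURE_BEAD_AREA = 60.0  # A^2 nominal exposed area per one-bead site


def _one_bead_etr(target_kcal: float, area: float, geom) -> float:
    """Per-area energy making E_IMP at z=0 equal the target exactly.

    Solves -S etr C0 + a_lip S C0 = target for etr, with C0 = C(0).
    """
    from .energy_core import membrane_profile

    c0 = membrane_profile(0.0, geom)
    return geom.a_lip - target_kcal / (area * c0)


def _helix_beads(residue_names: list[str], seed: int, geom) -> ParticleSystem:
    from .membrane_params import builtin_scale

    scale = builtin_scale()
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, 1e-3, size=(len(residue_names), 3))  # break exact symmetry
    particles = []
    n = len(residue_names)
    for i, res in enumerate(residue_names):
        theta = math.radians(HELIX_TWIST * i)
        pos = np.array(
            [
                HELIX_RADIUS * math.cos(theta),
                HELIX_RADIUS * math.sin(theta),
                HELIX_RISE * (i - (n - 1) / 2.0),
            ]
        ) + jitter[i]
        particles.append(
            Particle(
                id=i,
                position=pos,
                radius=DEFAULT_BEAD_RADIUS,
                sasa=FIXTURE_BEAD_AREA,
                etr_per_area=_one_bead_etr(scale[res], FIXTURE_BEAD_AREA, geom),
                type_label=res,
                residue_id=("A", res, i + 1),
                is_sidechain=True,
            )
        )
    return ParticleSystem(particles, "one-bead")


def make_fixture(kind: str, size: int = 18, seed: int = 0, geom=None) -> ParticleSystem:
    """Deterministic synthetic test systems.

    kind:
      toy_residue        `size` well-separated side-chain spheres (isolated
                         spheres, so per-particle SASA is analytic) behind a
                         single backbone site
      amphipathic_helix  ideal alpha-helix of `size` one-bead residues, LEU on
                         one face and SER on the other (period ~3.6)
      hydrophobic_helix  as above, all LEU
      barrel_shell       hollow particle cylinder of height `size` (A) with a
                         hydrophobic outer band in the middle and polar caps
    """
    from .membrane_params import MembraneGeometry, builtin_scale

    geom = geom or MembraneGeometry()
    if kind == "toy_residue":
        if not 1 <= size <= 50:
            raise ValueError("toy_residue size must be in [1, 50]")
        rng = np.random.default_rng(seed)
        spacing = 4.0 * (ELEMENT_RADII["C"] + DEFAULT_PROBE)
        particles = [
            Particle(
                id=0,
                position=np.array([-spacing, 0.0, 0.0]),
                radius=ELEMENT_RADII["N"],
                type_label="N",
                residue_id=("A", "TOY", 1),
                is_sidechain=False,
            )
        ]
        for i in range(size):
            particles.append(
                Particle(
                    id=i + 1,
                    position=np.array([i * spacing, 0.0, 0.0])
                    + rng.normal(0, 0.05, 3),
                    radius=ELEMENT_RADII["C"],
                    type_label="CB" if i == 0 else f"CG{i}",
                    residue_id=("A", "TOY", 1),
                    is_sidechain=True,
                )
            )
        return ParticleSystem(particles, "all-atom")

    if kind in ("amphipathic_helix", "hydrophobic_helix"):
        if not 6 <= size <= 200:
            raise ValueError("helix size must be in [6, 200] residues")
        if kind == "hydrophobic_helix":
            names = ["LEU"] * size
        else:
            # hydrophobic face at theta ~ 0: alternation with period 360/100 = 3.6;
            # lysine gives the polar face a strong aqueous preference, as in
            # natural surface-seeking amphipathic helices
            names = [
                "LEU" if math.cos(math.radians(HELIX_TWIST * i)) > 0 else "LYS"
                for i in range(size)
            ]
        return _helix_beads(names, seed, geom)

    if kind == "barrel_shell":
        height = float(size)
        if not 10.0 <= height <= 100.0:
            raise ValueError("barrel height must be in [10, 100] A")
        scale = builtin_scale()
        n_ring, ring_step, radius = 16, 2.0, 12.0
        n_levels = int(round(height / ring_step)) + 1
        zs = np.linspace(-height / 2.0, height / 2.0, n_levels)
        rng = np.random.default_rng(seed)
        jitter = rng.normal(0.0, 1e-3, size=(n_levels * n_ring, 3))
        particles = []
        band = min(13.5, height / 2.0 * 0.6)  # hydrophobic belt half-height
        for li, z in enumerate(zs):
            for k in range(n_ring):
                theta = 2.0 * math.pi * (k + 0.5 * (li % 2)) / n_ring
                i = len(particles)
                res = "LEU" if abs(z) <= band else "LYS"
                particles.append(
                    Particle(
                        id=i,
                        position=np.array(
                            [radius * math.cos(theta), radius * math.sin(theta), z]
                        )
                        + jitter[i],
                        radius=DEFAULT_BEAD_RADIUS,
                        sasa=FIXTURE_BEAD_AREA,
                        etr_per_area=_one_bead_etr(scale[res], FIXTURE_BEAD_AREA, geom),
                        type_label=res,
                        residue_id=("A", res, i + 1),
                        is_sidechain=True,
                    )
                )
        return ParticleSystem(particles, "one-bead")

    raise ValueError(
        f"unknown fixture kind {kind!r}; "
        "use toy_residue, amphipathic_helix, hydrophobic_helix or barrel_shell"
    )
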