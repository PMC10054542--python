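"""Lipid structural parameterization of the implicit bilayer.

The implicit membrane is a one-dimensional sigmoidal field C(z) whose shape is
set by three structural parameters: the interface steepness ``alpha``, the
position ``z0`` of the center of the lipid-headgroup region, and the headgroup
width ``beta``.  These can be derived from two experimentally measurable
bilayer thicknesses — the hydrocarbon thickness 2D_C and the steric thickness
D_B' — via

    beta  = (D_B' - 2D_C) / 2
    z0    = (D_B' - beta) / 2
    alpha = 2 ln(88.0145) / beta

The constant 88.0145 (:data:`SIGMOID_SPAN`) encodes the historical pairing
alpha = 1.99 for beta = 4.5 A: exp(1.99 * 4.5 / 2) ~= 88.0145.  A fourth
parameter ``a_lip`` (kcal mol-1 A-2) scales the lipid-perturbation energy term
and is not derivable from structure.

This module also houses the preset geometries for seven common phospholipids
and the hydrophobicity-scale registry (per-residue water->membrane transfer
free energies; negative = hydrophobic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

__all__ = [
    "SIGMOID_SPAN",
    "KCAL_TO_KJ",
    "MembraneGeometry",
    "LipidStructuralParams",
    "HydrophobicityScale",
    "derive_geometry",
    "get_preset",
    "list_presets",
    "convert_energy",
    "load_scale",
    "save_scale",
    "builtin_scale",
]

#: Sigmoid span constant relating alpha and beta: alpha = 2 ln(SIGMOID_SPAN)/beta.
SIGMOID_SPAN = 88.0145

#: Thermochemical calorie: 1 kcal = 4.184 kJ.
KCAL_TO_KJ = 4.184

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up, the convention of printed parameter tables.

    Derived z0 values often end exactly in ...5 at the third decimal (they
    are quarter-sums of one-decimal thicknesses); binary floats would round
    some of them down.  Values are first snapped to 9 decimals so that float
    accumulation error (e.g. 15.774999999999999 for the exact 15.775) does
    not defeat the half-up rule.
    """
    d = Decimal(repr(value)).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


class InvalidLipidError(ValueError):
    """Raised when structural thicknesses imply a non-positive headgroup width."""


@dataclass(frozen=True)
class MembraneGeometry:
    """One implicit bilayer: (alpha, z0, beta, a_lip).

    alpha : interface steepness (treated as unitless)
    z0    : center of the headgroup region (A)
    beta  : headgroup region width (A)
    a_lip : lipid perturbation coefficient (kcal mol-1 A-2)
    """

    alpha: float = 1.99
    z0: float = 15.75
    beta: float = 4.5
    a_lip: float = -0.018
    label: str = "default"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.z0 <= 0 or self.beta <= 0:
            raise ValueError(
                f"alpha, z0, beta must be positive, got "
                f"({self.alpha}, {self.z0}, {self.beta})"
            )


@dataclass(frozen=True)
class LipidStructuralParams:
    """Measured bilayer thicknesses for one lipid.

    hydrocarbon_thickness : 2D_C, acyl-core thickness (A)
    steric_thickness      : D_B', full steric bilayer thickness (A)
    temperature           : measurement temperature (deg C, metadata only)
    """

    hydrocarbon_thickness: float
    steric_thickness: float
    temperature: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.hydrocarbon_thickness < self.steric_thickness:
            raise InvalidLipidError(
                f"need steric_thickness > hydrocarbon_thickness > 0, got "
                f"2D_C={self.hydrocarbon_thickness}, D_B'={self.steric_thickness}"
            )


def derive_geometry(
    lipid: LipidStructuralParams, a_lip: float = -0.018
) -> MembraneGeometry:
    """Derive the sigmoid geometry (beta, z0, alpha) from bilayer thicknesses.

    z0 and alpha are computed from the *unrounded* beta; rounding only ever
    happens at presentation time.

    Raises
    ------
    InvalidLipidError
        If the thicknesses imply beta <= 0 (zero-width headgroup region).
    """
    beta = (lipid.steric_thickness - lipid.hydrocarbon_thickness) / 2.0
    if beta <= 0:
        raise InvalidLipidError(
            f"non-positive headgroup width beta={beta} for {lipid.name or 'lipid'}"
        )
    z0 = (lipid.steric_thickness - beta) / 2.0
    alpha = 2.0 * math.log(SIGMOID_SPAN) / beta
    return MembraneGeometry(
        alpha=alpha, z0=z0, beta=beta, a_lip=a_lip, label=lipid.name or "derived"
    )


#: Structural thicknesses (2D_C, D_B', T in deg C) for the preset lipids.
_LIPID_TABLE: dict[str, LipidStructuralParams] = {
    name: LipidStructuralParams(two_dc, dbp, temp, name)
    for name, two_dc, dbp, temp in [
        ("DLPG", 20.7, 35.3, 20),
        ("DOPC", 27.1, 35.9, 30),
        ("DMPC", 26.2, 36.9, 30),
        ("DLPE", 30.0, 42.1, 20),
        ("DOPG", 27.9, 42.8, 20),
        ("POPG", 28.3, 44.0, 20),
        ("DPPC", 34.4, 47.8, 20),
    ]
}


def lipid_structural_params(name: str) -> LipidStructuralParams:
    """Return the stored (2D_C, D_B') thicknesses for a preset lipid."""
    try:
        return _LIPID_TABLE[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown lipid {name!r}; available: {', '.join(list_presets())}"
        ) from None


def list_presets() -> list[str]:
    return [*_LIPID_TABLE, "default"]


def get_preset(name: str) -> MembraneGeometry:
    """Geometry preset by lipid name; ``"default"`` is the historical
    theoretical bilayer (alpha=1.99, z0=15.75, beta=4.5, a_lip=-0.018)."""
    if name.lower() == "default":
        return MembraneGeometry()
    return derive_geometry(lipid_structural_params(name))


# ---------------------------------------------------------------------------
# energy units

_UNIT_ALIASES = {
    "kcal/mol": ("kcal", False),
    "kj/mol": ("kj", False),
    "kcal/mol/a2": ("kcal", True),
    "kj/mol/a2": ("kj", True),
}


def _parse_unit(u: str) -> tuple[str, bool]:
    key = u.strip().lower().replace(" ", "").replace("å", "a").replace("^2", "2")
    key = key.replace("mol-1", "mol").replace("a-2", "/a2").replace("//", "/")
    if key not in _UNIT_ALIASES:
        raise ValueError(f"unrecognized energy unit {u!r}")
    return _UNIT_ALIASES[key]


def convert_energy(value: float, from_units: str, to_units: str) -> float:
    """Convert between kcal/mol and kJ/mol (and their per-A^2 variants).

    Raises on a dimension mismatch (per-area vs molar).
    """
    f_base, f_area = _parse_unit(from_units)
    t_base, t_area = _parse_unit(to_units)
    if f_area != t_area:
        raise ValueError(
            f"cannot convert {from_units!r} to {to_units!r}: per-area dimension differs"
        )
    if f_base == t_base:
        return value
    return value * KCAL_TO_KJ if f_base == "kcal" else value / KCAL_TO_KJ


# ---------------------------------------------------------------------------
# hydrophobicity scales


@dataclass
class HydrophobicityScale:
    """Per-residue water->membrane transfer free energies.

    Negative values are hydrophobic (membrane-favoring).  A complete scale
    covers the 20 standard residues, but partial scales are allowed for
    targeted calibration.
    """

    name: str
    units: str = "kcal/mol"
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _parse_unit(self.units)
        self.values = {k.upper(): float(v) for k, v in self.values.items()}

    def __getitem__(self, residue: str) -> float:
        return self.values[residue.upper()]

    def __contains__(self, residue: str) -> bool:
        return residue.upper() in self.values

    def residues(self) -> list[str]:
        return list(self.values)

    @property
    def complete(self) -> bool:
        return all(r in self.values for r in STANDARD_RESIDUES)

    def in_units(self, units: str) -> "HydrophobicityScale":
        vals = {r: convert_energy(v, self.units, units) for r, v in self.values.items()}
        return HydrophobicityScale(self.name, units, vals)


def load_scale(path: str | Path, name: str | None = None) -> HydrophobicityScale:
    """Read a two-column (residue, energy) scale file.

    Format: optional ``# units: kcal/mol`` header line; data lines are
    whitespace/tab-delimited ``RES value``.  Lines starting with ``#`` are
    comments.  Units default to kcal/mol when no header is present.
    """
    path = Path(path)
    units = "kcal/mol"
    values: dict[str, float] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            low = line.lstrip("#").strip().lower()
            if low.startswith("units"):
                units = low.split(":", 1)[1].strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed scale line in {path}: {raw!r}")
        values[parts[0].upper()] = float(parts[1])
    if not values:
        raise ValueError(f"no scale entries found in {path}")
    return HydrophobicityScale(name or path.stem, units, values)


def save_scale(scale: HydrophobicityScale, path: str | Path) -> None:
    lines = [f"# units: {scale.units}"]
    lines += [f"{r}\t{v:.6g}" for r, v in scale.values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# Octanol/water side-chain partition free energies in the style of the
# Fauchere-Pliska measurements (kcal/mol; negative = hydrophobic).  Shipped
# as a realistic built-in for calibration exercises; any user scale file is
# equally accepted.
_BUILTIN_SCALES: dict[str, Mapping[str, float]] = {
    "fauchere-pliska": {
        "ALA": -0.31, "ARG": 1.01, "ASN": 0.60, "ASP": 0.77, "CYS": -1.54,
        "GLN": 0.22, "GLU": 0.64, "GLY": 0.00, "HIS": -0.13, "ILE": -1.80,
        "LEU": -1.70, "LYS": 0.99, "MET": -1.23, "PHE": -1.79, "PRO": -0.72,
        "SER": 0.04, "THR": -0.26, "TRP": -2.25, "TYR": -0.96, "VAL": -1.22,
    },
}


def builtin_scale(name: str = "fauchere-pliska") -> HydrophobicityScale:
    """A shipped reference scale (sign convention: negative = hydrophobic)."""
    try:
        vals = _BUILTIN_SCALES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown built-in scale {name!r}; available: {list(_BUILTIN_SCALES)}"
        ) from None
    return HydrophobicityScale(name.lower(), "kcal/mol", dict(vals))
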