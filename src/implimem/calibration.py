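"""Per-residue reparameterization of transfer energies against any scale.

The insertion energy is linear in the per-type transfer energies, so for a
residue whose side chain exposes surface in types t the predicted transfer
energy at the bilayer center is

    E_pred = sum_t A_t E_t + B

with A_t = mean over conformations of -sum_{i in t} S_i C(z_i) and
B = mean of a_lip sum_i S_i C(z_i) (side-chain atoms only, side-chain
centroid at z = 0).  Any target scale value T is then reached exactly by a
closed-form update; four strategies differ in *which* minimal change they
make:

    least_norm     E' = E + A (T - E_pred) / ||A||^2   (minimal L2 change)
    proportional   E' = lambda E, lambda = (T - B)/(E_pred - B)
                   (preserves pairwise ratios between type energies)
    single_type    adjusts only the type with the largest |A_t|
    uniform_shift  equal additive shift on all types with A_t != 0
    auto           runs all four, keeps the one with minimal MAAPE

Deviation from the initial parameters is scored with the mean arctangent
absolute percent error, MAAPE = (1/n) sum arctan(|(U_i - I_i)/U_i|) * 100
(radians), and the "fewest changes" selection keeps the strategy minimizing
it.  A fixed-point iterative mode is provided for parity with iterative
fitting; it converges to the same solutions the closed forms give directly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformations import ConformationDB
from .energy_core import ParticleSystem, membrane_profile, predict_transfer_energy
from .membrane_params import HydrophobicityScale, MembraneGeometry
from .structures import AtomTypeParams, assign_atom_types, compute_sasa

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "STRATEGIES",
    "prepare_conformations",
    "linearize",
    "calibrate_residue",
    "maape",
    "calibrate_scale",
    "partition_to_per_area",
]

STRATEGIES = ("least_norm", "proportional", "single_type", "uniform_shift")

TOLERANCE = 1e-6  # kcal/mol, on |achieved - target|


class UnsolvableError(ValueError):
    """The residue exposes no side-chain surface: no parameter can move E_pred."""


@dataclass
class CalibrationProblem:
    """One residue's calibration: conformations, initial params, target."""

    residue: str
    conformations: list[ParticleSystem]      # typed, SASA'd, centered
    initial_params: dict[str, float]         # type -> E_tr per area
    target_energy: float                     # kcal/mol
    geometry: MembraneGeometry = field(default_factory=MembraneGeometry)

    def __post_init__(self) -> None:
        if not self.conformations:
            raise ValueError(f"{self.residue}: need at least one conformation")
        if not math.isfinite(self.target_energy):
            raise ValueError(f"{self.residue}: target energy must be finite")


@dataclass
class CalibrationResult:
    residue: str
    adjusted_params: dict[str, float]
    achieved_energy: float
    strategy: str
    maape: float

    def __post_init__(self) -> None:
        pass  # tolerance is asserted by the caller against the problem target


def prepare_conformations(
    db: ConformationDB,
    residue: str,
    params: AtomTypeParams,
    geom: MembraneGeometry,
) -> list[ParticleSystem]:
    """Type, SASA and center the stored conformations of a residue.

    SASA is computed on the full residue (backbone occludes the side chain),
    then each conformation is translated so the side-chain centroid sits at
    z = 0, the pose at which transfer energies are defined.
    """
    out = []
    for conf in db[residue]:
        c = conf.copy()
        assign_atom_types(c, params)
        compute_sasa(c)
        sc = c.sidechain()
        if len(sc):
            c = c.translated([0.0, 0.0, -sc.center_of_mass()[2]])
        out.append(c)
    return out


def linearize(problem: CalibrationProblem) -> tuple[dict[str, float], float]:
    """Coefficients (A_t, B) of E_pred = sum_t A_t E_t + B for this residue.

    Raises UnsolvableError when every A_t is zero (no exposed side-chain
    surface to calibrate).
    """
    geom = problem.geometry
    acc_a: dict[str, float] = {}
    acc_b = 0.0
    n = len(problem.conformations)
    for conf in problem.conformations:
        sc = conf.sidechain()
        if len(sc) == 0:
            continue
        c = membrane_profile(sc.positions[:, 2], geom)
        s = sc.sasa_array()
        labels = [p.type_label for p in sc]
        for lab in set(labels):
            mask = np.array([l == lab for l in labels])
            acc_a[lab] = acc_a.get(lab, 0.0) + float(-np.sum(s[mask] * c[mask])) / n
        acc_b += float(geom.a_lip * np.sum(s * c)) / n
    if not acc_a or all(abs(v) < 1e-12 for v in acc_a.values()):
        raise UnsolvableError(
            f"{problem.residue}: no exposed side-chain surface; cannot calibrate"
        )
    return acc_a, acc_b


def maape(adjusted, initial) -> float:
    """Mean arctangent absolute percent error between parameter vectors.

    (1/n) sum arctan(|(U_i - I_i)/U_i|) * 100, arctangent in radians; U is
    the adjusted vector.  A zero adjusted entry uses a capped ratio
    |U_i - I_i| / 1e-12 (logged), pushing that term toward arctan(inf).
    """
    u = np.asarray(adjusted, dtype=float)
    i = np.asarray(initial, dtype=float)
    if u.shape != i.shape:
        raise ValueError("adjusted and initial vectors differ in length")
    if u.size == 0:
        raise ValueError("empty parameter vectors")
    denom = u.copy()
    zero = denom == 0.0
    if zero.any():
        logger.info("maape: %d zero adjusted entries, ratio capped", int(zero.sum()))
        denom[zero] = 1e-12
    return float(np.mean(np.arctan(np.abs((u - i) / denom))) * 100.0)


def _solve(strategy: str, a: np.ndarray, b: float, e0: np.ndarray, target: float):
    """Closed-form adjusted energies for one strategy; None if inapplicable."""
    pred = float(a @ e0 + b)
    gap = target - pred
    if strategy == "least_norm":
        return e0 + a * gap / float(a @ a)
    if strategy == "proportional":
        if abs(pred - b) < 1e-12:
            return None
        return e0 * ((target - b) / (pred - b))
    if strategy == "single_type":
        k = int(np.argmax(np.abs(a)))
        out = e0.copy()
        out[k] += gap / a[k]
        return out
    if strategy == "uniform_shift":
        nz = np.abs(a) > 1e-12
        total = float(a[nz].sum())
        if abs(total) < 1e-12:
            return None
        out = e0.copy()
        out[nz] += gap / total
        return out
    raise ValueError(f"unknown strategy {strategy!r}")


def calibrate_residue(
    problem: CalibrationProblem,
    strategy: str = "auto",
    iterative: bool = False,
    max_iter: int = 200,
) -> CalibrationResult:
    """Adjust this residue's type energies so E_pred hits the target.

    strategy is one of the four closed forms or "auto" (all four, minimal
    MAAPE wins).  If proportional is undefined (E_pred == B) it falls through
    to least_norm with a warning.  With iterative=True the chosen strategy's
    constraint is reached by damped fixed-point iteration instead of the
    closed form (same solution, for parity with iterative fitters).
    """
    coeffs, b = linearize(problem)
    types = sorted(coeffs)
    a = np.array([coeffs[t] for t in types])
    e0 = np.array([problem.initial_params[t] for t in types])
    target = problem.target_energy

    names = STRATEGIES if strategy == "auto" else (strategy,)
    candidates: list[tuple[float, str, np.ndarray]] = []
    for name in names:
        e1 = _solve(name, a, b, e0, target)
        if e1 is None:
            warnings.warn(
                f"{problem.residue}: {name} undefined (E_pred == B); using least_norm"
            )
            e1 = _solve("least_norm", a, b, e0, target)
        if iterative:
            e1 = _fixed_point(a, b, e0, e1, target, max_iter)
        candidates.append((maape(e1, e0), name, e1))
    score, name, e1 = min(candidates, key=lambda c: c[0])

    achieved = float(a @ e1 + b)
    if abs(achieved - target) > TOLERANCE:
        raise RuntimeError(
            f"{problem.residue}: calibration missed target by "
            f"{abs(achieved - target):.2e} kcal/mol"
        )
    return CalibrationResult(
        residue=problem.residue,
        adjusted_params=dict(zip(types, e1.tolist())),
        achieved_energy=achieved,
        strategy=name,
        maape=score,
    )


def _fixed_point(a, b, e0, e_direction, target, max_iter):
    """Damped iteration toward the same constraint surface the closed form
    solves; steps along (e_direction - e0) with an under-relaxed gain."""
    e = e0.astype(float).copy()
    step = e_direction - e0
    lam = 0.0
    for _ in range(max_iter):
        pred = float(a @ e + b)
        if abs(pred - target) <= TOLERANCE / 10:
            return e
        lam += 0.5 * (1.0 - lam)  # geometric approach to lam = 1
        e = e0 + lam * step
    return e_direction  # closed form as the fixed point


def calibrate_scale(
    scale: HydrophobicityScale,
    db: ConformationDB,
    initial: AtomTypeParams,
    geom: MembraneGeometry = MembraneGeometry(),
    strategy: str = "auto",
) -> tuple[AtomTypeParams, pd.DataFrame]:
    """Calibrate every residue of a scale; returns (params, report).

    The report has one row per scale residue: target, prediction with the
    initial parameters, prediction after calibration, winning strategy and
    MAAPE.  Per-residue failures are collected into the report (status
    column), not fatal.
    """
    scale_kcal = scale.in_units("kcal/mol")
    out = initial.copy()
    rows = []
    for res in scale_kcal.residues():
        row = {"residue": res, "target": scale_kcal[res]}
        try:
            confs = prepare_conformations(db, res, initial, geom)
            types = sorted(
                {p.type_label for c in confs for p in c.sidechain()}
            )
            problem = CalibrationProblem(
                residue=res,
                conformations=confs,
                initial_params=initial.residue_slice(res, types),
                target_energy=scale_kcal[res],
                geometry=geom,
            )
            row["initial_prediction"] = np.mean(
                [predict_transfer_energy(c, geom, center=False) for c in confs]
            )
            result = calibrate_residue(problem, strategy=strategy)
            for t, v in result.adjusted_params.items():
                out.set(res, t, v)
            row.update(
                calibrated_prediction=result.achieved_energy,
                strategy=result.strategy,
                maape=result.maape,
                status="ok",
            )
        except (KeyError, UnsolvableError, ValueError) as exc:
            logger.warning("calibration failed for %s: %s", res, exc)
            row.update(
                calibrated_prediction=np.nan, strategy="", maape=np.nan,
                status=f"failed: {exc}",
            )
        rows.append(row)
    return out, pd.DataFrame(rows)


def partition_to_per_area(dg: float, bead_area: float) -> float:
    """Partition free energy -> per-area bead transfer energy (same energy
    units per A^2).  Used to turn hexadecane/octanol partition values into
    coarse-grained correspondence tables."""
    if bead_area <= 0:
        raise ValueError(f"bead area must be positive, got {bead_area}")
    return dg / bead_area
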