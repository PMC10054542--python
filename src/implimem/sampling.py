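"""Rigid-body Monte Carlo, gradient relaxation and insertion analytics.

A protein is moved as a rigid body in the implicit membrane: uniform random
translations (per-axis, within +-max_translation) and rotations about a
random axis through the center of mass (uniform angle within +-max_rotation),
accepted with the Metropolis criterion min(1, exp(-dE_IMP/kT)).  The
membrane argument is pluggable — analytic planar, analytic double, or
mesh-based — exactly as in the energy layer.

Also provided: a steepest-descent rigid relaxation, an elastic-network model
(harmonic springs between all particle pairs within a cutoff, default 9 A)
for flexible refinement, and the standard insertion analytics: signed depth
of the center of mass, tilt of a declared insertion vector against the local
membrane normal, roll about that vector, per-residue depth profiles and
insertion-energy scans.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .energy_core import (
    EnergyBreakdown,
    ParticleSystem,
    _resolve_membrane,
    energy_gradient,
    planar_depth,
    total_energy,
)
from .membrane_params import MembraneGeometry

__all__ = [
    "BOLTZMANN_KCAL",
    "Pose",
    "Trajectory",
    "ElasticNetwork",
    "DepthProfile",
    "run_monte_carlo",
    "minimize",
    "MinimizeResult",
    "build_enm",
    "insertion_metrics",
    "depth_profile",
    "energy_scan",
]

#: Boltzmann constant in kcal mol-1 K-1.
BOLTZMANN_KCAL = 0.0019872


@dataclass
class Pose:
    """Rigid-body pose: x -> R x + t, with optional derived insertion metrics."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: Rotation = field(default_factory=Rotation.identity)
    depth: float | None = None
    tilt: float | None = None
    roll: float | None = None

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return self.rotation.apply(positions) + self.translation

    @property
    def quaternion(self) -> np.ndarray:
        q = self.rotation.as_quat()
        return q / np.linalg.norm(q)


@dataclass
class TrajectoryFrame:
    step: int
    pose: Pose
    energy: EnergyBreakdown
    accepted: bool


@dataclass
class Trajectory:
    """Recorded Monte Carlo run: frames plus the parameters that made it."""

    frames: list[TrajectoryFrame] = field(default_factory=list)
    seed: int | None = None
    parameters: dict = field(default_factory=dict)
    n_accepted: int = 0
    n_steps: int = 0

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / self.n_steps if self.n_steps else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "step": f.step,
                "depth": f.pose.depth,
                "tilt": f.pose.tilt,
                "roll": f.pose.roll,
                "e_int": f.energy.e_int,
                "e_lip": f.energy.e_lip,
                "e_imp": f.energy.e_imp,
                "accepted": f.accepted,
            }
            for f in self.frames
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, **self.parameters}, fh, indent=1)


def _metrics_for(
    positions: np.ndarray,
    membrane,
    geom: MembraneGeometry,
    vector_pair: tuple[int, int] | None,
    reference_axis: np.ndarray,
) -> tuple[float, float | None, float | None]:
    depth_fn, _, _, _ = _resolve_membrane(membrane, geom)
    com = positions.mean(axis=0)
    z, normals = depth_fn(com.reshape(1, 3))
    depth = float(z[0])
    if vector_pair is None:
        return depth, None, None
    a, b = vector_pair
    vec = positions[b] - positions[a]
    nv = np.linalg.norm(vec)
    if nv < 1e-9:
        raise ValueError("insertion vector degenerate (coincident particles)")
    vec = vec / nv
    n = np.asarray(normals[0], dtype=float)
    tilt = math.degrees(math.acos(min(1.0, abs(float(vec @ n)))))
    # roll: signed rotation about the insertion vector between the projected
    # reference axis and the projected local normal
    ref = np.asarray(reference_axis, dtype=float)
    ref_p = ref - (ref @ vec) * vec
    n_p = n - (n @ vec) * vec
    if np.linalg.norm(ref_p) < 1e-9 or np.linalg.norm(n_p) < 1e-9:
        roll = 0.0
    else:
        ref_p /= np.linalg.norm(ref_p)
        n_p /= np.linalg.norm(n_p)
        roll = math.degrees(
            math.atan2(float(np.cross(ref_p, n_p) @ vec), float(ref_p @ n_p))
        )
        if roll <= -180.0:
            roll += 360.0
    return depth, tilt, roll


def run_monte_carlo(
    system: ParticleSystem,
    membrane=planar_depth,
    temperature: float = 300.0,
    steps: int = 10000,
    max_translation: float = 1.0,
    max_rotation: float = 5.0,
    seed: int = 0,
    geom: MembraneGeometry = MembraneGeometry(),
    record_every: int = 10,
    vector_pair: tuple[int, int] | None = None,
    reference_axis=(1.0, 0.0, 0.0),
) -> Trajectory:
    """Metropolis Monte Carlo of a rigid body in an implicit membrane.

    Moves combine a uniform per-axis translation within +-max_translation (A)
    and a rotation about a random axis through the center of mass by a
    uniform angle within +-max_rotation (deg).  Identical seeds give bitwise
    identical trajectories.  Raises on a non-finite energy, dumping the pose.
    """
    if temperature <= 0 or steps <= 0:
        raise ValueError("temperature and steps must be positive")
    rng = np.random.default_rng(seed)
    kt = BOLTZMANN_KCAL * temperature

    work = system.copy()
    pos = work.positions
    rot = Rotation.identity()
    trans = np.zeros(3)
    energy = total_energy(work, membrane, geom)
    if not math.isfinite(energy.e_imp):
        raise RuntimeError(f"non-finite starting energy at pose t={trans}")

    traj = Trajectory(
        seed=seed,
        parameters={
            "temperature_K": temperature,
            "steps": steps,
            "max_translation_A": max_translation,
            "max_rotation_deg": max_rotation,
            "record_every": record_every,
        },
    )

    def record(step: int, accepted: bool) -> None:
        d, t, r = _metrics_for(pos, membrane, geom, vector_pair, reference_axis)
        traj.frames.append(
            TrajectoryFrame(
                step,
                Pose(trans.copy(), rot, depth=d, tilt=t, roll=r),
                energy,
                accepted,
            )
        )

    record(0, True)
    for step in range(1, steps + 1):
        dt = rng.uniform(-max_translation, max_translation, size=3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.uniform(-max_rotation, max_rotation))
        rmove = Rotation.from_rotvec(angle * axis)

        com = pos.mean(axis=0)
        new_pos = rmove.apply(pos - com) + com + dt
        work.positions = new_pos
        new_energy = total_energy(work, membrane, geom)
        if not math.isfinite(new_energy.e_imp):
            raise RuntimeError(
                f"non-finite energy at step {step}; pose translation={trans + dt}"
            )
        de = new_energy.e_imp - energy.e_imp
        accepted = de <= 0 or rng.random() < math.exp(max(-de / kt, -700.0))
        if accepted:
            pos = new_pos
            energy = new_energy
            # affine composition: x -> Rm (R x + t - com) + com + dt
            rot = rmove * rot
            trans = rmove.apply(trans - com) + com + dt
            traj.n_accepted += 1
        else:
            work.positions = pos
        if step % record_every == 0:
            record(step, accepted)
    traj.n_steps = steps
    return traj


@dataclass
class MinimizeResult:
    pose: Pose
    energy: EnergyBreakdown
    n_iterations: int
    converged: bool
    system: ParticleSystem


def minimize(
    system: ParticleSystem,
    membrane=planar_depth,
    geom: MembraneGeometry = MembraneGeometry(),
    step_size: float = 0.5,
    max_iterations: int = 2000,
    tolerance: float = 1e-9,
    enm: "ElasticNetwork | None" = None,
) -> MinimizeResult:
    """Steepest-descent relaxation; rigid translation by default.

    The system is translated along its net membrane force until the energy
    change falls below tolerance; on an uphill proposal the step is halved
    (logged via the returned iteration count).  With an ElasticNetwork the
    descent acts per particle on membrane + spring forces instead.
    """
    work = system.copy()

    def objective() -> tuple[EnergyBreakdown, float]:
        e = total_energy(work, membrane, geom)
        extra = enm.energy(work.positions) if enm is not None else 0.0
        return e, e.e_imp + extra

    energy, score = objective()
    step = step_size
    trans = np.zeros(3)
    n = 0
    converged = False
    for n in range(1, max_iterations + 1):
        forces = energy_gradient(work, membrane, geom)
        if enm is not None:
            forces = forces + enm.forces(work.positions)
            new_pos = work.positions + np.clip(step * forces, -2.0, 2.0)
        else:
            net = forces.sum(axis=0)
            norm = np.linalg.norm(net)
            if norm < 1e-12:
                converged = True
                break
            new_pos = work.positions + step * net / norm
        prev = work.positions
        move = new_pos[0] - prev[0]
        work.positions = new_pos
        new_energy, new_score = objective()
        if new_score < score:
            if enm is None:
                trans = trans + move
            done = abs(new_score - score) < tolerance
            energy, score = new_energy, new_score
            if done:
                converged = True
                break
        else:
            # uphill proposal: oscillation around the minimum -> halve the step
            work.positions = prev
            step *= 0.5
            if step < 1e-9:
                converged = True
                break
    d, _, _ = _metrics_for(work.positions, membrane, geom, None, (1, 0, 0))
    return MinimizeResult(
        pose=Pose(trans, Rotation.identity(), depth=d),
        energy=energy,
        n_iterations=n,
        converged=converged,
        system=work,
    )


# ---------------------------------------------------------------------------
# elastic network


@dataclass
class ElasticNetwork:
    """Harmonic springs (i, j, rest length, stiffness) within a cutoff."""

    pairs: np.ndarray          # (M, 2) int, i < j
    rest_lengths: np.ndarray   # (M,) A
    stiffness: float           # kcal mol-1 A-2
    cutoff: float

    def energy(self, positions: np.ndarray) -> float:
        """Sum of 1/2 k (d - d0)^2 over springs."""
        if len(self.pairs) == 0:
            return 0.0
        d = np.linalg.norm(
            positions[self.pairs[:, 0]] - positions[self.pairs[:, 1]], axis=1
        )
        return float(0.5 * self.stiffness * np.sum((d - self.rest_lengths) ** 2))

    def forces(self, positions: np.ndarray) -> np.ndarray:
        out = np.zeros_like(positions)
        if len(self.pairs) == 0:
            return out
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        dvec = positions[i] - positions[j]
        d = np.linalg.norm(dvec, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        f = (-self.stiffness * (d - self.rest_lengths) / d)[:, None] * dvec
        np.add.at(out, i, f)
        np.add.at(out, j, -f)
        return out


def build_enm(
    system: ParticleSystem, cutoff: float = 9.0, stiffness: float = 1.0
) -> ElasticNetwork:
    """Elastic network over all unique particle pairs within the cutoff.

    Rest lengths are the build-time distances, so the network energy and net
    force are exactly zero at the build geometry.
    """
    pos = system.positions
    pairs = np.array(sorted(cKDTree(pos).query_pairs(cutoff)), dtype=int)
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    rest = (
        np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        if len(pairs)
        else np.zeros(0)
    )
    return ElasticNetwork(pairs, rest, stiffness, cutoff)


# ---------------------------------------------------------------------------
# analytics


def insertion_metrics(
    system: ParticleSystem,
    membrane=planar_depth,
    vector_pair: tuple[int, int] | None = None,
    reference_axis=(1.0, 0.0, 0.0),
    geom: MembraneGeometry = MembraneGeometry(),
) -> tuple[float, float | None, float | None]:
    """(depth, tilt, roll) of the current pose.

    depth — signed depth of the center of mass (A); tilt — angle of the
    insertion vector against the local membrane normal, folded to [0, 90]
    deg; roll — rotation about the insertion vector relative to the declared
    reference axis, in (-180, 180] deg.
    """
    return _metrics_for(
        system.positions, membrane, geom, vector_pair, np.asarray(reference_axis)
    )


@dataclass
class DepthProfile:
    """Per-residue mean signed depth, optionally against a reference."""

    residues: list[int]
    mean_depth: np.ndarray
    reference: np.ndarray | None = None

    @property
    def deviation(self) -> np.ndarray | None:
        if self.reference is None:
            return None
        return self.mean_depth - self.reference

    def to_dataframe(self) -> pd.DataFrame:
        data = {"residue": self.residues, "mean_depth": self.mean_depth}
        if self.reference is not None:
            data["reference"] = self.reference
            data["deviation"] = self.deviation
        return pd.DataFrame(data)


def depth_profile(
    system: ParticleSystem,
    membrane=planar_depth,
    geom: MembraneGeometry = MembraneGeometry(),
    selection: list[int] | None = None,
    trajectory: Trajectory | None = None,
    window: slice = slice(None),
    reference: dict[int, float] | None = None,
) -> DepthProfile:
    """Per-residue mean signed depth (the EPR-style insertion plot quantity).

    With a trajectory, depths are averaged over the recorded poses in
    ``window`` applied to the *initial* coordinates; otherwise the
    instantaneous depths of the current pose are used.  ``reference`` maps
    residue number to a reference depth for per-residue deviations.
    """
    depth_fn, _, _, _ = _resolve_membrane(membrane, geom)
    resnums = [p.residue_id[2] for p in system]
    order: list[int] = []
    for r in resnums:
        if r not in order:
            order.append(r)
    if selection is not None:
        order = [r for r in order if r in set(selection)]
        if not order:
            raise ValueError("selection matches no residues")
    groups = {r: [i for i, rn in enumerate(resnums) if rn == r] for r in order}

    if trajectory is not None:
        frames = trajectory.frames[window]
        if not frames:
            raise ValueError("empty trajectory window")
        base = system.positions
        per_frame = []
        for f in frames:
            z, _ = depth_fn(f.pose.apply(base))
            per_frame.append(z)
        z_mean = np.mean(per_frame, axis=0)
    else:
        z_mean, _ = depth_fn(system.positions)

    means = np.array([np.mean([z_mean[i] for i in groups[r]]) for r in order])
    ref = (
        np.array([reference.get(r, np.nan) for r in order])
        if reference is not None
        else None
    )
    return DepthProfile(order, means, ref)


def energy_scan(
    system: ParticleSystem,
    membrane=planar_depth,
    geom: MembraneGeometry = MembraneGeometry(),
    axis=(0.0, 0.0, 1.0),
    scan_range: tuple[float, float] = (-40.0, 40.0),
    step: float = 1.0,
) -> pd.DataFrame:
    """Rigid translation along an axis with energies tabulated per offset.

    Returns a DataFrame (coordinate, e_int, e_lip, e_imp); the scan minimum
    locates insertion barriers and stable depths along the chosen direction.
    """
    lo, hi = scan_range
    if hi <= lo or step <= 0:
        raise ValueError("invalid scan range/step")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    offsets = np.arange(lo, hi + step / 2, step)
    work = system.copy()
    base = work.positions
    rows = []
    for c in offsets:
        work.positions = base + c * axis
        e = total_energy(work, membrane, geom)
        rows.append({"coordinate": float(c), **e.as_dict()})
    return pd.DataFrame(rows)
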