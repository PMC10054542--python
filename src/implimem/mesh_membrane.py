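"""Membranes of arbitrary shape, defined by a triangulated midplane mesh.

Instead of an analytic reference plane, the bilayer midplane (the z = 0
surface of the profile C) is a triangulated mesh.  Each particle's signed
depth z_i is measured to its nearest mesh vertex, with the sign set by the
vertex normal: a particle on the normal side of the surface has positive
depth.  Two depth modes are provided:

``projection`` (default)
    z_i = (p - v) . n(v) — the component of the offset along the vertex
    normal.  Exact on planar meshes at any resolution.
``euclidean``
    z_i = sign((p - v) . n(v)) |p - v| — the full Euclidean distance with a
    normal-side sign.  On coarse meshes this overestimates |z_i| by up to the
    grid half-diagonal, reproducing the resolution-dependent error of
    nearest-point schemes.

Nearest-vertex queries go through a uniform spatial hash with an expanding
ring search, built once per mesh.  Multiple membranes are simply multiple
meshes: a particle is assigned the mesh giving the smallest |z_i|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .membrane_params import MembraneGeometry
from .energy_core import membrane_profile, membrane_profile_derivative

__all__ = [
    "MembraneMesh",
    "SpatialHash",
    "generate_planar_mesh",
    "apply_spherical_curvature",
    "load_mesh",
    "save_mesh",
    "nearest_vertex",
    "signed_depth",
    "mesh_insertion_geometry",
    "MeshMembraneField",
    "MultiMeshField",
]


@dataclass
class MembraneMesh:
    """Triangulated membrane midplane with per-vertex unit normals.

    A generated planar grid with xSize columns and ySize rows has
    (xSize+1)(ySize+1) vertices and xSize*ySize*2 triangles, all normals on
    the same side of the surface.
    """

    vertices: np.ndarray          # (N, 3) A
    triangles: np.ndarray         # (M, 3) int vertex indices, consistent winding
    normals: np.ndarray = None    # (N, 3) unit vectors
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if len(self.vertices) == 0:
            raise ValueError("mesh has no vertices")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")
        if self.normals is None:
            self.normals = vertex_normals(self.vertices, self.triangles)
        else:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            norms = np.linalg.norm(self.normals, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("zero-length vertex normal")
            self.normals = self.normals / norms

    @property
    def bounds(self) -> np.ndarray:
        """Axis-aligned bounding box, shape (2, 3): [min, max]."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def mean_edge_length(self) -> float:
        if not len(self.triangles):
            return 1.0
        v = self.vertices
        t = self.triangles
        e = np.concatenate(
            [
                np.linalg.norm(v[t[:, 0]] - v[t[:, 1]], axis=1),
                np.linalg.norm(v[t[:, 1]] - v[t[:, 2]], axis=1),
                np.linalg.norm(v[t[:, 2]] - v[t[:, 0]], axis=1),
            ]
        )
        return float(e.mean())


def vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted average of incident-triangle normals, renormalized.

    The triangle cross product carries the area weight, so summing raw cross
    products per vertex is exactly the area weighting.
    """
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    out = np.zeros_like(vertices)
    if len(triangles):
        a = vertices[triangles[:, 0]]
        cross = np.cross(vertices[triangles[:, 1]] - a, vertices[triangles[:, 2]] - a)
        for k in range(3):
            np.add.at(out, triangles[:, k], cross)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    out[zero] = (0.0, 0.0, 1.0)   # isolated vertex: arbitrary but unit
    norms[zero] = 1.0
    return out / norms


def generate_planar_mesh(size_x: float, size_y: float, resolution: float) -> MembraneMesh:
    """Planar midplane grid at z=0, centered on the origin.

    xSize = floor(size_x/resolution) column intervals (and likewise ySize),
    giving (xSize+1)(ySize+1) vertices and 2*xSize*ySize triangles wound so
    every triangle normal is +z.
    """
    if size_x <= 0 or size_y <= 0 or resolution <= 0:
        raise ValueError("sizes and resolution must be positive")
    x_size = math.floor(size_x / resolution)
    y_size = math.floor(size_y / resolution)
    if x_size < 1 or y_size < 1:
        raise ValueError(
            f"resolution {resolution} A exceeds mesh size ({size_x} x {size_y} A)"
        )
    xs = (np.arange(x_size + 1) - x_size / 2.0) * resolution
    ys = (np.arange(y_size + 1) - y_size / 2.0) * resolution
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])

    def vid(i: int, j: int) -> int:
        return i * (y_size + 1) + j

    tris = []
    for i in range(x_size):
        for j in range(y_size):
            # counter-clockwise seen from +z -> triangle normals all +z
            tris.append((vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)))
            tris.append((vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)))
    return MembraneMesh(vertices, np.array(tris, dtype=int), resolution=resolution)


def apply_spherical_curvature(
    mesh: MembraneMesh, radius: float, sign: int = 1
) -> MembraneMesh:
    """Bend a mesh onto a sphere: vertex z set to sign*sqrt(r^2-x^2-y^2) - r.

    x, y are measured from the mesh center; curvature is 1/radius, so a very
    large radius leaves the mesh essentially flat.  Normals are recomputed
    from the curved triangle geometry.

    Raises if any vertex lies outside the disk x^2+y^2 <= r^2, reporting the
    minimal admissible radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    center = mesh.vertices[:, :2].mean(axis=0)
    xy = mesh.vertices[:, :2] - center
    rho2 = (xy**2).sum(axis=1)
    r_min = math.sqrt(rho2.max())
    if r_min > radius:
        raise ValueError(
            f"vertex at lateral distance {r_min:.3f} A outside sphere; "
            f"minimal admissible radius is {r_min:.3f} A"
        )
    z = sign * np.sqrt(radius**2 - rho2) - radius
    vertices = mesh.vertices.copy()
    vertices[:, 2] = z
    return MembraneMesh(vertices, mesh.triangles.copy(), resolution=mesh.resolution)


# ---------------------------------------------------------------------------
# file I/O (OBJ / PLY, ASCII) — format parsing delegated to trimesh


def load_mesh(path: str | Path) -> MembraneMesh:
    """Read an OBJ or PLY mesh as a membrane midplane.

    Degenerate (zero-area) triangles are dropped with a logged count;
    inconsistent winding triggers a warning and automatic reorientation.
    Vertex normals are recomputed from the triangle geometry.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing mesh file: {path}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ValueError(f"cannot parse mesh file {path}: {exc}") from exc
    if not hasattr(tm, "vertices") or len(tm.vertices) == 0:
        raise ValueError(f"no vertices parsed from {path}")
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=int).reshape(-1, 3) if len(tm.faces) else np.zeros((0, 3), int)

    # drop degenerate triangles
    if len(faces):
        a = vertices[faces[:, 0]]
        areas = 0.5 * np.linalg.norm(
            np.cross(vertices[faces[:, 1]] - a, vertices[faces[:, 2]] - a), axis=1
        )
        keep = areas > 1e-12
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} degenerate triangles from {path.name}")
            faces = faces[keep]

    # reorient to consistent winding if needed
    if len(faces):
        clean = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        before = clean.faces.copy()
        trimesh.repair.fix_normals(clean)
        if not np.array_equal(before, clean.faces):
            warnings.warn(f"inconsistent triangle winding in {path.name}; reoriented")
        faces = np.asarray(clean.faces, dtype=int)
    return MembraneMesh(vertices, faces)


def save_mesh(mesh: MembraneMesh, path: str | Path) -> None:
    """Write the mesh as ASCII OBJ or PLY (chosen by extension)."""
    path = Path(path)
    tm = trimesh.Trimesh(
        vertices=mesh.vertices,
        faces=mesh.triangles,
        vertex_normals=mesh.normals,
        process=False,
    )
    suffix = path.suffix.lower()
    if suffix == ".obj":
        path.write_text(tm.export(file_type="obj"))
    elif suffix == ".ply":
        data = tm.export(file_type="ply", encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        raise ValueError(f"unsupported mesh format {suffix!r} (use .obj or .ply)")


# ---------------------------------------------------------------------------
# nearest-vertex queries via a uniform spatial hash


class SpatialHash:
    """Uniform grid hash over mesh vertices for nearest-vertex queries.

    Every vertex lives in exactly one cubic cell of side ``cell_size``.  A
    query expands Chebyshev rings around the query point's (clamped) cell
    until candidates appear, then widens by the found distance to guarantee
    the true nearest vertex; ties break to the lowest vertex index.
    """

    def __init__(self, mesh: MembraneMesh, cell_size: float | None = None):
        if mesh.n_vertices == 0:
            raise ValueError("cannot hash an empty mesh")
        if cell_size is None:
            cell_size = (
                2.0 * mesh.resolution
                if mesh.resolution is not None
                else max(mesh.mean_edge_length(), 1e-6)
            )
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.cell_size = float(cell_size)
        self.mesh = mesh
        cells = np.floor(mesh.vertices / self.cell_size).astype(np.int64)
        self._cells: dict[tuple[int, int, int], list[int]] = {}
        for idx, c in enumerate(map(tuple, cells)):
            self._cells.setdefault(c, []).append(idx)
        self._lo = cells.min(axis=0)
        self._hi = cells.max(axis=0)

    def _ring_cells(self, center: np.ndarray, r: int):
        """Cells on the Chebyshev shell of radius r, clipped to occupied bounds."""
        lo = np.maximum(center - r, self._lo)
        hi = np.minimum(center + r, self._hi)
        for ix in range(lo[0], hi[0] + 1):
            for iy in range(lo[1], hi[1] + 1):
                for iz in range(lo[2], hi[2] + 1):
                    if max(abs(ix - center[0]), abs(iy - center[1]), abs(iz - center[2])) == r:
                        yield (ix, iy, iz)

    def query(self, point: np.ndarray) -> tuple[int, float]:
        """(index, distance) of the nearest vertex to ``point``."""
        point = np.asarray(point, dtype=float)
        raw = np.floor(point / self.cell_size).astype(np.int64)
        center = np.clip(raw, self._lo, self._hi)
        cheb_offset = int(np.abs(raw - center).max())
        # worst case: scan every occupied cell
        stop = int((self._hi - self._lo).max()) + 1 + cheb_offset

        best_idx, best_d2 = -1, np.inf
        r = 0
        while r <= stop:
            for cell in ([tuple(center)] if r == 0 else self._ring_cells(center, r)):
                ids = self._cells.get(cell)
                if not ids:
                    continue
                pts = self.mesh.vertices[ids]
                d2 = ((pts - point) ** 2).sum(axis=1)
                k = int(np.argmin(d2))   # ids ascend, so ties pick lowest index
                if d2[k] < best_d2 or (d2[k] == best_d2 and ids[k] < best_idx):
                    best_idx, best_d2 = ids[k], d2[k]
            if best_idx >= 0:
                # the Euclidean ball of the best distance around the query
                # point only reaches cells this far (Chebyshev) from center
                needed = cheb_offset + int(math.ceil(math.sqrt(best_d2) / self.cell_size)) + 1
                stop = min(stop, needed)
            r += 1
        if best_idx < 0:
            raise RuntimeError("spatial hash query failed (empty mesh?)")
        return best_idx, float(math.sqrt(best_d2))


def nearest_vertex(point: np.ndarray, mesh: MembraneMesh, hash: SpatialHash | None = None) -> int:
    """Index of the Euclidean-nearest mesh vertex (ties -> lowest index)."""
    if hash is None:
        hash = SpatialHash(mesh)
    return hash.query(point)[0]


def signed_depth(
    point: np.ndarray,
    mesh: MembraneMesh,
    hash: SpatialHash | None = None,
    mode: str = "projection",
) -> float:
    """Signed depth of a point relative to the mesh midplane.

    The sign comes from the side of the surface the point lies on — i.e.
    whether the offset vector makes an angle within (-90, 90) degrees with
    the nearest vertex's normal.
    """
    if hash is None:
        hash = SpatialHash(mesh)
    point = np.asarray(point, dtype=float)
    idx, dist = hash.query(point)
    offset = point - mesh.vertices[idx]
    along = float(offset @ mesh.normals[idx])
    if mode == "projection":
        return along
    if mode == "euclidean":
        if along == 0.0:
            return 0.0
        return math.copysign(dist, along)
    raise ValueError(f"unknown depth mode {mode!r}")


def mesh_insertion_geometry(
    system,
    vector_pair: tuple[int, int],
    mesh: MembraneMesh,
    hash: SpatialHash | None = None,
    mode: str = "projection",
) -> tuple[float, float]:
    """(depth, tilt) of a particle system relative to a mesh membrane.

    depth : signed depth of the system's center of mass (A)
    tilt  : angle between the insertion vector (particle b - particle a) and
            the membrane normal at the COM's nearest vertex, folded into
            [0, 90] degrees.  Reduces to the planar-frame angle on a flat
            mesh.
    """
    if hash is None:
        hash = SpatialHash(mesh)
    a, b = vector_pair
    vec = np.asarray(system[b].position - system[a].position, dtype=float)
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise ValueError(f"insertion vector undefined: particles {a} and {b} coincide")
    com = system.center_of_mass()
    depth = signed_depth(com, mesh, hash, mode=mode)
    n = mesh.normals[hash.query(com)[0]]
    cosang = abs(float(vec @ n)) / norm
    tilt = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
    return depth, tilt


# ---------------------------------------------------------------------------
# pluggable membrane field built on a mesh


class MeshMembraneField:
    """Mesh-backed membrane for the energy machinery.

    Exposes .depth / .profile / .profile_derivative / .geom, so it slots into
    total_energy, energy_gradient and the samplers exactly like the analytic
    membranes.
    """

    def __init__(
        self,
        mesh: MembraneMesh,
        geom: MembraneGeometry = MembraneGeometry(),
        mode: str = "projection",
        cell_size: float | None = None,
    ):
        if mode not in ("projection", "euclidean"):
            raise ValueError(f"unknown depth mode {mode!r}")
        self.mesh = mesh
        self.geom = geom
        self.mode = mode
        self.hash = SpatialHash(mesh, cell_size)

    def depth(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        z = np.empty(len(positions))
        normals = np.empty_like(positions)
        for k, p in enumerate(positions):
            idx, dist = self.hash.query(p)
            n = self.mesh.normals[idx]
            along = float((p - self.mesh.vertices[idx]) @ n)
            if self.mode == "projection":
                z[k] = along
            else:
                z[k] = math.copysign(dist, along) if along != 0.0 else 0.0
            normals[k] = n
        return z, normals

    def profile(self, z):
        return membrane_profile(z, self.geom)

    def profile_derivative(self, z):
        return membrane_profile_derivative(z, self.geom)


class MultiMeshField:
    """Several mesh membranes; each particle uses the mesh of smallest |depth|."""

    def __init__(self, fields: list[MeshMembraneField]):
        if not fields:
            raise ValueError("need at least one mesh field")
        self.fields = fields
        self.geom = fields[0].geom

    def depth(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        zs, ns = zip(*(f.depth(positions) for f in self.fields))
        zs = np.stack(zs)                       # (F, N)
        ns = np.stack(ns)                       # (F, N, 3)
        pick = np.abs(zs).argmin(axis=0)        # (N,)
        cols = np.arange(zs.shape[1])
        return zs[pick, cols], ns[pick, cols]

    def profile(self, z):
        return membrane_profile(z, self.geom)

    def profile_derivative(self, z):
        return membrane_profile_derivative(z, self.geom)
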