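"""Triangulated particle surfaces: generators, topology, I/O.

Meshes must be closed, orientable and consistently wound with outward
normals (positive enclosed volume); the boundary-element solver checks
these invariants before assembling.  Sphere meshes are geodesic icosahedra
with an arbitrary subdivision frequency ``nu`` (``20 nu^2`` triangles),
which allows element counts between the powers of four of plain subdivision.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["TriMesh", "icosphere", "cube_mesh", "dimer", "load_mesh", "save_mesh"]


@dataclass(frozen=True)
class TriMesh:
    """An indexed triangle surface (vertices in nm)."""

    vertices: np.ndarray   # (Nv, 3) float
    faces: np.ndarray      # (Nt, 3) int, CCW seen from outside

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=int))

    # -- geometry ----------------------------------------------------------
    @cached_property
    def face_corners(self) -> np.ndarray:
        return self.vertices[self.faces]          # (Nt, 3, 3)

    @cached_property
    def face_normals_area(self):
        c = self.face_corners
        cr = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        area2 = np.linalg.norm(cr, axis=1)
        return cr / area2[:, None], 0.5 * area2

    @property
    def normals(self) -> np.ndarray:
        return self.face_normals_area[0]

    @property
    def areas(self) -> np.ndarray:
        return self.face_normals_area[1]

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.face_corners.mean(axis=1)

    @cached_property
    def volume(self) -> float:
        """Signed enclosed volume (positive for outward winding)."""
        c = self.face_corners
        return float(np.einsum("ij,ij->", c[:, 0], np.cross(c[:, 1], c[:, 2])) / 6.0)

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        c = self.face_corners
        return np.linalg.norm(np.roll(c, -1, axis=1) - c, axis=2).ravel()

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- topology ----------------------------------------------------------
    @cached_property
    def edge_table(self):
        """Unique edges and the two (face, local-slot) incidences of each.

        Local slot ``a`` is the edge opposite vertex ``a`` of the face,
        i.e. the edge (v_{a+1}, v_{a+2}).  Returns ``(edges, face_of,
        slot_of, sense)`` where ``sense`` is +1 for the face traversing the
        edge in its stored vertex order.
        """
        f = self.faces
        pairs = np.stack(
            [np.stack([f[:, 1], f[:, 2]], 1),
             np.stack([f[:, 2], f[:, 0]], 1),
             np.stack([f[:, 0], f[:, 1]], 1)],
            axis=1,
        ).reshape(-1, 2)                          # (3 Nt, 2) slot-major per face
        key = np.sort(pairs, axis=1)
        uniq, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        if not np.all(counts == 2):
            raise ValueError("mesh is not closed (every edge needs 2 faces)")
        order = np.argsort(inv, kind="stable")
        face_of = np.empty((len(uniq), 2), dtype=int)
        slot_of = np.empty((len(uniq), 2), dtype=int)
        sense = np.empty((len(uniq), 2), dtype=int)
        flat_face = order // 3
        flat_slot = order % 3
        fwd = (pairs[order, 0] == uniq[inv[order], 0]).astype(int) * 2 - 1
        face_of[:, 0], face_of[:, 1] = flat_face[0::2], flat_face[1::2]
        slot_of[:, 0], slot_of[:, 1] = flat_slot[0::2], flat_slot[1::2]
        sense[:, 0], sense[:, 1] = fwd[0::2], fwd[1::2]
        if np.any(sense.sum(axis=1) != 0):
            raise ValueError("mesh is not consistently oriented")
        return uniq, face_of, slot_of, sense

    @property
    def n_edges(self) -> int:
        return len(self.edge_table[0])

    @property
    def euler_characteristic(self) -> int:
        return len(self.vertices) - self.n_edges + self.n_faces

    def validate(self, require_outward: bool = True):
        """Raise on open/inconsistent meshes; check outward normals."""
        self.edge_table
        if require_outward and self.volume <= 0:
            raise ValueError("normals point inward (non-positive enclosed volume)")

    def translated(self, r0) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(r0, dtype=float), self.faces)

    def scaled(self, s: float) -> "TriMesh":
        return TriMesh(self.vertices * float(s), self.faces)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _icosahedron():
    t = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v[0])
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return v, f


def icosphere(diameter_nm: float, frequency: int = 3) -> TriMesh:
    """Geodesic sphere with ``20 * frequency**2`` triangles.

    All vertices lie exactly on the sphere of the requested diameter.
    """
    if diameter_nm <= 0 or frequency < 1:
        raise ValueError("need positive diameter and frequency >= 1")
    nu = int(frequency)
    base_v, base_f = _icosahedron()
    verts: list[np.ndarray] = []
    faces: list[list[int]] = []
    lookup: dict[tuple, int] = {}

    def vid(p):
        key = tuple(np.round(p * 1e7).astype(int))
        if key not in lookup:
            lookup[key] = len(verts)
            verts.append(p)
        return lookup[key]

    for tri in base_f:
        A, B, C = base_v[tri]
        # lattice of barycentric points, projected to the sphere
        grid = {}
        for i in range(nu + 1):
            for j in range(nu + 1 - i):
                p = (i * A + j * B + (nu - i - j) * C) / nu
                p = p / np.linalg.norm(p)
                grid[(i, j)] = vid(p)
        for i in range(nu):
            for j in range(nu - i):
                faces.append([grid[(i, j)], grid[(i + 1, j)], grid[(i, j + 1)]])
                if j < nu - i - 1:
                    faces.append(
                        [grid[(i + 1, j)], grid[(i + 1, j + 1)], grid[(i, j + 1)]]
                    )
    mesh = TriMesh(np.array(verts) * (0.5 * diameter_nm), np.array(faces))
    if mesh.volume < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    mesh.validate()
    return mesh


def cube_mesh(edge_nm: float, n_per_edge: int = 6) -> TriMesh:
    """Axis-aligned cube centred at the origin, ``12 n^2`` triangles."""
    if edge_nm <= 0 or n_per_edge < 1:
        raise ValueError("need positive edge length and subdivision")
    n = int(n_per_edge)
    h = 0.5 * edge_nm
    verts: list[np.ndarray] = []
    faces: list[list[int]] = []
    lookup: dict[tuple, int] = {}

    def vid(p):
        key = tuple(np.round(np.asarray(p) * 1e7).astype(int))
        if key not in lookup:
            lookup[key] = len(verts)
            verts.append(np.asarray(p, dtype=float))
        return lookup[key]

    # each face: origin corner, two edge vectors chosen so u x v = outward
    axes = [
        ([+h, -h, -h], [0, 2 * h, 0], [0, 0, 2 * h]),   # +x
        ([-h, -h, -h], [0, 0, 2 * h], [0, 2 * h, 0]),   # -x
        ([-h, +h, -h], [0, 0, 2 * h], [2 * h, 0, 0]),   # +y
        ([-h, -h, -h], [2 * h, 0, 0], [0, 0, 2 * h]),   # -y
        ([-h, -h, +h], [2 * h, 0, 0], [0, 2 * h, 0]),   # +z
        ([-h, -h, -h], [0, 2 * h, 0], [2 * h, 0, 0]),   # -z
    ]
    for orig, u, v in axes:
        orig, u, v = np.array(orig), np.array(u) / n, np.array(v) / n
        for i in range(n):
            for j in range(n):
                p00 = vid(orig + i * u + j * v)
                p10 = vid(orig + (i + 1) * u + j * v)
                p01 = vid(orig + i * u + (j + 1) * v)
                p11 = vid(orig + (i + 1) * u + (j + 1) * v)
                faces.append([p00, p10, p11])
                faces.append([p00, p11, p01])
    mesh = TriMesh(np.array(verts), np.array(faces))
    mesh.validate()
    return mesh


def dimer(
    diameter_nm: float, gap_nm: float, frequency: int = 6, axis=(1.0, 0.0, 0.0)
) -> tuple[TriMesh, TriMesh]:
    """Two spheres with centre separation ``diameter + gap`` along ``axis``."""
    if gap_nm <= 0:
        raise ValueError("dimer gap must be positive")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    half = 0.5 * (diameter_nm + gap_nm)
    base = icosphere(diameter_nm, frequency)
    return base.translated(-half * ax), base.translated(+half * ax)


# ---------------------------------------------------------------------------
# I/O (delegated to trimesh)
# ---------------------------------------------------------------------------

def load_mesh(path) -> TriMesh:
    """Read an OBJ/STL surface and validate it for the solver."""
    import trimesh as _tm

    m = _tm.load_mesh(str(path), process=True)
    mesh = TriMesh(np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=int))
    if mesh.volume < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    mesh.validate()
    return mesh


def save_mesh(mesh: TriMesh, path):
    """Write OBJ or STL depending on the file suffix."""
    import trimesh as _tm

    _tm.Trimesh(mesh.vertices, mesh.faces, process=False).export(str(path))
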