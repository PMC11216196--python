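"""Triangle meshes, BVH construction and nearest-hit ray casting.

The scene surface is a triangle soup in a local metric frame (typically a
Poisson reconstruction of a photogrammetric dense cloud).  Such meshes are
not watertight, have inconsistent winding, and commonly contain sliver
faces; the caster therefore hits both face sides, excludes degenerate
faces, and treats "miss" as an ordinary outcome rather than an error.

Intersection is Möller–Trumbore per triangle under an axis-aligned
bounding-volume hierarchy (median split on the longest centroid axis,
leaves of at most 4 faces), which is deterministic for a given mesh.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numba
import numpy as np
import trimesh as _trimesh

from .camera import Ray

__all__ = [
    "TriangleMesh",
    "RayHit",
    "BVH",
    "MeshLoadError",
    "load_mesh",
    "build_bvh",
    "intersect_first_hit",
]

#: faces with area below this (m^2) are flagged invalid and never hit
DEGENERATE_AREA = 1e-12

#: default minimum hit distance (m), avoids self-intersection at the origin
DEFAULT_T_MIN = 1e-6

#: two hits closer than this along the ray are a tie; the lower face index wins
_T_TIE = 1e-12


class MeshLoadError(ValueError):
    """Raised for malformed or unsupported mesh files."""


@dataclass
class TriangleMesh:
    """Indexed triangle soup with per-face validity flags.

    ``face_valid`` marks faces with area >= ``DEGENERATE_AREA``; only valid
    faces participate in ray casting.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {self.faces.shape}")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            bad = int(np.argmax((self.faces < 0) | (self.faces >= n)).item() // 3)
            raise ValueError(
                f"face {bad} references a vertex index outside [0, {n})"
            )
        if self.face_valid is None:
            self.face_valid = self._compute_valid()
        else:
            self.face_valid = np.asarray(self.face_valid, dtype=bool)

    def _compute_valid(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area = 0.5 * np.linalg.norm(cross, axis=1)
        return area >= DEGENERATE_AREA

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_valid_faces(self) -> int:
        return int(self.face_valid.sum())


@dataclass(frozen=True)
class RayHit:
    """First intersection of a ray with the mesh."""

    face_index: int
    t: float
    point: np.ndarray
    barycentric: tuple[float, float, float]


def load_mesh(path: str | os.PathLike) -> TriangleMesh:
    """Load an OBJ or PLY file as a :class:`TriangleMesh`.

    OBJ is parsed directly (``v``/``f`` records; texture and normal indices
    in ``a/b/c`` face tokens are ignored; quads are split ``(0,1,2)(0,2,3)``
    and larger polygons fan-triangulated).  PLY (ASCII or binary
    little-endian) goes through :mod:`trimesh`.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if not os.path.exists(path):
        raise MeshLoadError(f"mesh file not found: {path}")
    if ext == ".obj":
        return _load_obj(path)
    if ext == ".ply":
        try:
            tm = _trimesh.load(path, file_type="ply", process=False, force="mesh")
        except Exception as exc:  # malformed header / truncated body
            raise MeshLoadError(f"cannot read PLY file {path}: {exc}") from exc
        try:
            return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        except ValueError as exc:
            raise MeshLoadError(f"invalid mesh in {path}: {exc}") from exc
    raise MeshLoadError(f"unknown mesh extension {ext!r} (expected .obj or .ply): {path}")


def _load_obj(path: str) -> TriangleMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshLoadError(f"{path}:{lineno}: vertex record needs 3 coordinates")
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise MeshLoadError(f"{path}:{lineno}: bad vertex coordinate") from exc
            elif tag == "f":
                idx: list[int] = []
                for tok in parts[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise MeshLoadError(f"{path}:{lineno}: bad face index {tok!r}") from exc
                    if i < 0:
                        i = len(vertices) + i  # relative OBJ indexing
                    else:
                        i = i - 1
                    if i < 0 or i >= len(vertices):
                        raise MeshLoadError(
                            f"{path}:{lineno}: face index {tok!r} out of range "
                            f"(mesh has {len(vertices)} vertices so far)"
                        )
                    idx.append(i)
                if len(idx) < 3:
                    raise MeshLoadError(f"{path}:{lineno}: face needs at least 3 vertices")
                for k in range(1, len(idx) - 1):
                    faces.append([idx[0], idx[k], idx[k + 1]])
            # other records (vt, vn, usemtl, ...) are ignored
    if not vertices:
        raise MeshLoadError(f"{path}: no vertices found")
    return TriangleMesh(np.array(vertices), np.array(faces).reshape(-1, 3))


class BVH:
    """Axis-aligned bounding-volume hierarchy over a mesh's valid faces.

    Built by recursive median split on the centroid of the longest axis;
    ties in centroid coordinate are broken by face index so the structure
    is fully deterministic for a given mesh.
    """

    def __init__(self, mesh: TriangleMesh, leaf_size: int = 4):
        if mesh.n_valid_faces == 0:
            raise ValueError("cannot build a BVH on a mesh with no valid faces")
        self.mesh = mesh
        self.leaf_size = int(leaf_size)

        valid = np.flatnonzero(mesh.face_valid)
        tri = mesh.vertices[mesh.faces[valid]]
        self._face_ids = valid  # original face indices, parallel to tri
        self._v0 = tri[:, 0]
        self._e1 = tri[:, 1] - tri[:, 0]
        self._e2 = tri[:, 2] - tri[:, 0]
        self._box_min = tri.min(axis=1)
        self._box_max = tri.max(axis=1)
        centroids = tri.mean(axis=1)

        # flat node arrays; children stored as indices, -1 marks "leaf"
        self._node_min: list[np.ndarray] = []
        self._node_max: list[np.ndarray] = []
        self._node_left: list[int] = []
        self._node_right: list[int] = []
        self._node_start: list[int] = []
        self._node_count: list[int] = []
        self._order = np.arange(len(valid))
        self._build(0, len(valid), centroids)
        self._node_min_arr = np.array(self._node_min)
        self._node_max_arr = np.array(self._node_max)
        self._node_left_arr = np.array(self._node_left, dtype=np.int64)
        self._node_right_arr = np.array(self._node_right, dtype=np.int64)
        self._node_start_arr = np.array(self._node_start, dtype=np.int64)
        self._node_count_arr = np.array(self._node_count, dtype=np.int64)
        self._depth = self._max_depth(0)

    def _max_depth(self, node: int) -> int:
        if self._node_count[node] > 0:
            return 1
        return 1 + max(
            self._max_depth(self._node_left[node]),
            self._max_depth(self._node_right[node]),
        )

    def _new_node(self, lo: int, hi: int) -> int:
        sel = self._order[lo:hi]
        self._node_min.append(self._box_min[sel].min(axis=0))
        self._node_max.append(self._box_max[sel].max(axis=0))
        self._node_left.append(-1)
        self._node_right.append(-1)
        self._node_start.append(lo)
        self._node_count.append(hi - lo)
        return len(self._node_min) - 1

    def _build(self, lo: int, hi: int, centroids: np.ndarray) -> int:
        node = self._new_node(lo, hi)
        if hi - lo <= self.leaf_size:
            return node
        sel = self._order[lo:hi]
        c = centroids[sel]
        extent = c.max(axis=0) - c.min(axis=0)
        axis = int(np.argmax(extent))
        # stable sort on (centroid, face index) for determinism
        order = np.lexsort((sel, c[:, axis]))
        self._order[lo:hi] = sel[order]
        mid = lo + (hi - lo) // 2
        self._node_count[node] = 0  # internal
        self._node_left[node] = self._build(lo, mid, centroids)
        self._node_right[node] = self._build(mid, hi, centroids)
        return node

    @property
    def n_nodes(self) -> int:
        return len(self._node_min)


def build_bvh(mesh: TriangleMesh, leaf_size: int = 4) -> BVH:
    """Build the spatial index used by :func:`intersect_first_hit`."""
    return BVH(mesh, leaf_size=leaf_size)


@numba.njit(cache=True)
def _traverse(
    origin,
    direction,
    node_min,
    node_max,
    node_left,
    node_right,
    node_start,
    node_count,
    order,
    face_ids,
    v0,
    e1,
    e2,
    t_min,
    max_depth,
):  # pragma: no cover - exercised through intersect_first_hit
    """Nearest-hit BVH traversal; returns (face_id, t, u, v) or face_id = -1."""
    tie = 1e-12
    best_t = np.inf
    best_face = np.int64(-1)
    best_u = 0.0
    best_v = 0.0
    inv = np.empty(3)
    for a in range(3):
        inv[a] = 1.0 / direction[a] if direction[a] != 0.0 else np.inf

    stack = np.empty(2 * max_depth + 2, dtype=np.int64)
    top = 0
    stack[top] = 0
    top += 1
    while top > 0:
        top -= 1
        node = stack[top]
        # slab test against the node AABB
        tmin = 0.0
        tmax = np.inf
        miss = False
        for a in range(3):
            if np.isinf(inv[a]):
                if origin[a] < node_min[node, a] or origin[a] > node_max[node, a]:
                    miss = True
                    break
            else:
                ta = (node_min[node, a] - origin[a]) * inv[a]
                tb = (node_max[node, a] - origin[a]) * inv[a]
                if ta > tb:
                    ta, tb = tb, ta
                if ta > tmin:
                    tmin = ta
                if tb < tmax:
                    tmax = tb
                if tmax < tmin:
                    miss = True
                    break
        if miss or tmin > best_t + tie:
            continue
        count = node_count[node]
        if count == 0:
            stack[top] = node_right[node]
            top += 1
            stack[top] = node_left[node]
            top += 1
            continue
        lo = node_start[node]
        for k in range(count):
            f = order[lo + k]
            # Möller–Trumbore, both winding orders accepted
            px = direction[1] * e2[f, 2] - direction[2] * e2[f, 1]
            py = direction[2] * e2[f, 0] - direction[0] * e2[f, 2]
            pz = direction[0] * e2[f, 1] - direction[1] * e2[f, 0]
            det = e1[f, 0] * px + e1[f, 1] * py + e1[f, 2] * pz
            if abs(det) < 1e-14:
                continue
            inv_det = 1.0 / det
            tx = origin[0] - v0[f, 0]
            ty = origin[1] - v0[f, 1]
            tz = origin[2] - v0[f, 2]
            u = (tx * px + ty * py + tz * pz) * inv_det
            if u < -1e-9:
                continue
            qx = ty * e1[f, 2] - tz * e1[f, 1]
            qy = tz * e1[f, 0] - tx * e1[f, 2]
            qz = tx * e1[f, 1] - ty * e1[f, 0]
            v = (direction[0] * qx + direction[1] * qy + direction[2] * qz) * inv_det
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            t = (e2[f, 0] * qx + e2[f, 1] * qy + e2[f, 2] * qz) * inv_det
            if t <= t_min:
                continue
            fid = face_ids[f]
            if t < best_t - tie or (abs(t - best_t) <= tie and fid < best_face):
                best_t = t
                best_face = fid
                best_u = u
                best_v = v
    return best_face, best_t, best_u, best_v


def intersect_first_hit(
    ray: Ray, mesh: TriangleMesh, bvh: BVH, t_min: float = DEFAULT_T_MIN
) -> RayHit | None:
    """Nearest intersection of a ray with the mesh, or ``None`` on a miss.

    Returns the hit with the smallest ``t > t_min``; when two candidate
    hits are within 1e-12 m of each other along the ray the lower original
    face index wins, so results are deterministic.
    """
    if bvh.mesh is not mesh:
        raise ValueError("BVH was built on a different mesh")
    face, t, u, v = _traverse(
        ray.origin,
        ray.direction,
        bvh._node_min_arr,
        bvh._node_max_arr,
        bvh._node_left_arr,
        bvh._node_right_arr,
        bvh._node_start_arr,
        bvh._node_count_arr,
        bvh._order,
        bvh._face_ids,
        bvh._v0,
        bvh._e1,
        bvh._e2,
        t_min,
        bvh._depth,
    )
    if face < 0:
        return None
    return RayHit(
        face_index=int(face),
        t=float(t),
        point=ray.origin + t * ray.direction,
        barycentric=(1.0 - u - v, float(u), float(v)),
    )
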