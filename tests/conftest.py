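"""Shared fixtures and independent test oracles.

The oracle implementations here deliberately do not share code with the
package: ray/triangle intersection is a dense all-triangle scan, polygon
intersection is Sutherland–Hodgman clipping, and quantiles are computed
from the sorted-order definition directly.
"""

from __future__ import annotations

import numpy as np
import pytest

from annoray import (
    CameraIntrinsics,
    CameraPose,
    TriangleMesh,
    build_bvh,
)

R_NADIR = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])


@pytest.fixture
def nadir_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(
        focal_px=1000.0, principal_point=(500.0, 500.0), image_size=(1000, 1000)
    )


@pytest.fixture
def nadir_pose() -> CameraPose:
    """Camera at (0, 0, 10) looking straight down (+z_cam = -z_world)."""
    return CameraPose(rotation=R_NADIR, center=np.array([0.0, 0.0, 10.0]), image_id="nadir")


@pytest.fixture
def plane_mesh() -> tuple[TriangleMesh, object]:
    """A 40 x 40 m square plane at z = 0 (two triangles), with its BVH."""
    v = np.array(
        [[-20.0, -20.0, 0.0], [20.0, -20.0, 0.0], [20.0, 20.0, 0.0], [-20.0, 20.0, 0.0]]
    )
    f = np.array([[0, 1, 2], [0, 2, 3]])
    mesh = TriangleMesh(v, f)
    return mesh, build_bvh(mesh)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, det fixed to +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def brute_force_first_hit(origin, direction, mesh: TriangleMesh, t_min=1e-6):
    """All-triangle scan oracle: returns (face_index, t) of the nearest hit.

    Same nearest/tie semantics as the spec: smallest t > t_min, ties within
    1e-12 broken by lower face index.  Independent of the BVH code path.
    """
    tri = mesh.vertices[mesh.faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin[None, :] - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = (
        ok
        & mesh.face_valid
        & (u >= -1e-9)
        & (v >= -1e-9)
        & (u + v <= 1.0 + 1e-9)
        & (t > t_min)
    )
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return None
    order = idx[np.lexsort((idx, t[idx]))]
    best = order[0]
    for cand in order[1:]:
        if t[cand] - t[best] > 1e-12:
            break
        if cand < best:
            best = cand
    return int(best), float(t[best])


def clip_polygon(subject: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Sutherland–Hodgman: clip a polygon by a convex polygon (both (n, 2))."""
    def is_ccw(poly):
        x, y = poly[:, 0], poly[:, 1]
        return np.sum((np.roll(x, -1) - x) * (np.roll(y, -1) + y)) < 0

    if not is_ccw(clip):
        clip = clip[::-1]
    output = [tuple(p) for p in subject]
    for i in range(len(clip)):
        a, b = clip[i], clip[(i + 1) % len(clip)]
        inp, output = output, []
        if not inp:
            break
        def inside(p):
            return (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0]) >= 0
        def intersect(p, q):
            dx, dy = q[0] - p[0], q[1] - p[1]
            ex, ey = b[0] - a[0], b[1] - a[1]
            denom = ex * dy - ey * dx
            s = (ey * (p[0] - a[0]) - ex * (p[1] - a[1])) / denom
            return (p[0] + s * dx, p[1] + s * dy)
        for j, p in enumerate(inp):
            q = inp[(j + 1) % len(inp)]
            if inside(p):
                output.append(p)
                if not inside(q):
                    output.append(intersect(p, q))
            elif inside(q):
                output.append(intersect(p, q))
    return np.array(output) if output else np.empty((0, 2))


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area, absolute value."""
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def quantile_oracle(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile straight from the definition."""
    s = np.sort(np.asarray(values, dtype=float))
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return float(s[lo] + (h - lo) * (s[hi] - s[lo]))
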