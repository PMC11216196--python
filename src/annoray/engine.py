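"""Annotation reprojection: from 2D pixels to 3D positions on the mesh.

For every annotation vertex a viewing ray is cast from the camera center
through the (undistorted) pixel; the annotation's 3D position is the first
intersection of that ray with the scene mesh.  Rays that miss the mesh —
typically over unreconstructed holes or past the model boundary — cause
the annotation to be discarded (strict mode) or, for multi-vertex shapes,
optionally reduced to the surviving vertices (lenient mode).

Image footprints are obtained the same way by casting rays through the
image corners (optionally densified along the edges), and a reprojected
3D feature can be located back in every other image that sees it, with an
occlusion test against the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import (
    CameraIntrinsics,
    CameraPose,
    pixel_to_ray,
    project_point,
    scale_annotation_pixel,
)
from .formats import Annotation2D, Annotation3D, CameraView
from .geo import GeoAnchor, local_to_geodetic
from .mesh import BVH, TriangleMesh, intersect_first_hit

__all__ = [
    "Footprint",
    "LocateResult",
    "reproject_vertex",
    "reproject_annotation",
    "reproject_all",
    "georeference_annotations",
    "compute_footprint",
    "locate_in_images",
]

#: a point is considered visible if the first hit lands within this of it
#: (one order of magnitude below typical model resolution of ~5 mm ... 5 cm)
VISIBILITY_EPS = 1e-3


@dataclass
class Footprint:
    """3D polygon on the mesh covered by one image.

    Vertices run around the image boundary: top-left, top-right,
    bottom-right, bottom-left corners, with ``densify_n`` extra points per
    edge when requested.  ``complete`` means every boundary ray hit,
    ``partial`` at least three did, ``discarded`` fewer.
    """

    image_filename: str
    vertices_local: np.ndarray
    status: str
    vertices_geo: np.ndarray | None = None


@dataclass(frozen=True)
class LocateResult:
    """A camera that geometrically images a 3D point (maybe occluded)."""

    image_filename: str
    pixel: np.ndarray
    visible: bool


def reproject_vertex(
    pixel: tuple[float, float],
    intrinsics: CameraIntrinsics,
    pose: CameraPose,
    mesh: TriangleMesh,
    bvh: BVH,
) -> np.ndarray | None:
    """Cast the ray through one reconstruction-resolution pixel.

    Returns the first mesh intersection in the local frame, or ``None``
    when the ray misses the model.
    """
    ray = pixel_to_ray(pixel, intrinsics, pose)
    hit = intersect_first_hit(ray, mesh, bvh)
    return None if hit is None else hit.point


def reproject_annotation(
    annotation: Annotation2D,
    view: CameraView,
    mesh: TriangleMesh,
    bvh: BVH,
    mode: str = "strict",
) -> Annotation3D:
    """Reproject one annotation through its camera onto the mesh.

    Point: the single vertex is cast; a miss discards the annotation.
    Polygon/Rectangle/LineString: every vertex is cast; in ``strict`` mode
    (default) any miss discards the whole annotation, in ``lenient`` mode
    misses are dropped and the annotation survives as ``partial`` when at
    least three vertices remain.  Circle: the center and the rim point
    ``(cx + r, cy)`` are cast; the 3D radius is their distance.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    intr = view.intrinsics

    def to_recon(px: np.ndarray) -> np.ndarray:
        if annotation.annotated_image_size is not None:
            return scale_annotation_pixel(px, annotation.annotated_image_size, intr)
        return np.asarray(px, dtype=float)

    def discard() -> Annotation3D:
        return Annotation3D(
            annotation_id=annotation.annotation_id,
            label=annotation.label,
            status="discarded",
            vertices_local=np.empty((0, 3)),
            source_image=annotation.image_filename,
            shape=annotation.shape,
        )

    if annotation.shape == "Circle":
        cx, cy, r = annotation.points
        center = reproject_vertex(to_recon(np.array([cx, cy])), intr, view.pose, mesh, bvh)
        rim = reproject_vertex(to_recon(np.array([cx + r, cy])), intr, view.pose, mesh, bvh)
        if center is None:
            return discard()
        radius = float(np.linalg.norm(rim - center)) if rim is not None else None
        return Annotation3D(
            annotation_id=annotation.annotation_id,
            label=annotation.label,
            status="reprojected",
            vertices_local=center.reshape(1, 3),
            source_image=annotation.image_filename,
            shape="Circle",
            radius_m=radius,
        )

    hits: list[np.ndarray] = []
    n_miss = 0
    for px in annotation.vertices:
        p = reproject_vertex(to_recon(px), intr, view.pose, mesh, bvh)
        if p is None:
            n_miss += 1
        else:
            hits.append(p)
    if n_miss == 0:
        status = "reprojected"
    elif mode == "lenient" and len(hits) >= 3:
        status = "partial"
    else:
        return discard()
    return Annotation3D(
        annotation_id=annotation.annotation_id,
        label=annotation.label,
        status=status,
        vertices_local=np.array(hits),
        source_image=annotation.image_filename,
        shape=annotation.shape,
    )


def reproject_all(
    annotations: list[Annotation2D],
    views: list[CameraView],
    mesh: TriangleMesh,
    bvh: BVH,
    mode: str = "strict",
    case_insensitive_stems: bool = False,
) -> list[Annotation3D]:
    """Reproject a batch, matching each annotation to its camera by filename.

    Matching is exact by default; ``case_insensitive_stems`` enables a
    fallback on the lowercased filename stem.  An annotation whose image
    has no camera raises, listing the filename — silent fuzzy matching
    hides pairing bugs.  The conservation invariant
    ``len(input) == reprojected + partial + discarded`` holds by
    construction.
    """
    by_name = {v.image_filename: v for v in views}
    by_stem = {}
    if case_insensitive_stems:
        import os
        for v in views:
            by_stem[os.path.splitext(v.image_filename)[0].lower()] = v
    out: list[Annotation3D] = []
    for ann in annotations:
        view = by_name.get(ann.image_filename)
        if view is None and case_insensitive_stems:
            import os
            view = by_stem.get(os.path.splitext(ann.image_filename)[0].lower())
        if view is None:
            raise ValueError(
                f"no camera found for image {ann.image_filename!r} "
                f"(annotation {ann.annotation_id})"
            )
        out.append(reproject_annotation(ann, view, mesh, bvh, mode=mode))
    return out


def georeference_annotations(
    annotations: list[Annotation3D], anchor: GeoAnchor
) -> list[Annotation3D]:
    """Fill ``vertices_geo`` (WGS84 lat/lon/height) in place; returns the list."""
    for ann in annotations:
        if len(ann.vertices_local):
            ann.vertices_geo = local_to_geodetic(ann.vertices_local, anchor)
        else:
            ann.vertices_geo = np.empty((0, 3))
    return annotations


def _boundary_pixels(width: float, height: float, densify_n: int) -> np.ndarray:
    """Image-boundary pixels in order TL, (edge), TR, (edge), BR, (edge), BL, (edge)."""
    corners = [(0.0, 0.0), (width, 0.0), (width, height), (0.0, height)]
    pts: list[tuple[float, float]] = []
    for i in range(4):
        x0, y0 = corners[i]
        x1, y1 = corners[(i + 1) % 4]
        pts.append((x0, y0))
        for k in range(1, densify_n + 1):
            s = k / (densify_n + 1)
            pts.append((x0 + s * (x1 - x0), y0 + s * (y1 - y0)))
    return np.array(pts)


def compute_footprint(
    view: CameraView,
    mesh: TriangleMesh,
    bvh: BVH,
    densify_n: int = 0,
) -> Footprint:
    """Reproject the image boundary onto the mesh.

    ``densify_n`` extra boundary pixels per edge capture terrain relief
    that corner-only footprints miss; the default 0 casts the four corners
    only.
    """
    if densify_n < 0:
        raise ValueError("densify_n must be >= 0")
    w, h = view.intrinsics.image_size
    hits: list[np.ndarray] = []
    n_requested = 0
    for px in _boundary_pixels(float(w), float(h), densify_n):
        n_requested += 1
        p = reproject_vertex(px, view.intrinsics, view.pose, mesh, bvh)
        if p is not None:
            hits.append(p)
    if len(hits) == n_requested:
        status = "complete"
    elif len(hits) >= 3:
        status = "partial"
    else:
        status = "discarded"
    verts = np.array(hits) if hits else np.empty((0, 3))
    return Footprint(
        image_filename=view.image_filename, vertices_local=verts, status=status
    )


def locate_in_images(
    point_local: np.ndarray,
    views: list[CameraView],
    mesh: TriangleMesh,
    bvh: BVH,
    eps: float = VISIBILITY_EPS,
) -> list[LocateResult]:
    """Find every camera that images a 3D point, with an occlusion check.

    A camera is a candidate when the point projects in front of it and
    inside the image bounds; it is ``visible`` when the ray cast back
    through that pixel first hits the mesh within ``eps`` meters of the
    point (i.e. nothing occludes it).
    """
    p = np.asarray(point_local, dtype=float)
    results: list[LocateResult] = []
    for view in views:
        px = project_point(p, view.intrinsics, view.pose)
        if px is None:
            continue
        w, h = view.intrinsics.image_size
        if not (0.0 <= px[0] <= w and 0.0 <= px[1] <= h):
            continue
        hit = intersect_first_hit(pixel_to_ray(px, view.intrinsics, view.pose), mesh, bvh)
        visible = hit is not None and float(np.linalg.norm(hit.point - p)) <= eps
        results.append(LocateResult(view.image_filename, px, visible))
    return results
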