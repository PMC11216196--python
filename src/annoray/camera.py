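"""Pinhole camera model with Brown radial distortion.

Conventions (normative for the whole package):

* Pixel origin ``(0, 0)`` is the **top-left corner** of the image; ``u``
  grows to the right, ``v`` grows downward.  Annotation coordinates are
  continuous positions in this frame with no half-pixel shift, and the
  principal point uses the same convention.
* Camera frame: ``+x`` right, ``+y`` down, ``+z`` forward (the
  OpenCV/OpenMVG convention).  A world point ``X`` maps into the camera
  frame as ``x_c = R (X - C)`` where ``R`` is the world-to-camera rotation
  and ``C`` the camera optical center in the local metric model frame.
* Distortion is radial-only Brown ``(k1, k2, k3)``:
  ``d(r^2) = 1 + k1 r^2 + k2 r^4 + k3 r^6`` applied to normalized image
  coordinates.  Tangential terms are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "Ray",
    "UndistortionError",
    "project_point",
    "distort_normalized",
    "undistort_pixel",
    "pixel_to_ray",
    "scale_annotation_pixel",
]


class UndistortionError(RuntimeError):
    """Raised when the iterative undistortion fails to converge."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Optics of one camera at reconstruction resolution.

    Parameters
    ----------
    focal_px : float
        Focal length in pixels (square pixels assumed).
    principal_point : (float, float)
        ``(cx, cy)`` in pixels, top-left origin.
    image_size : (int, int)
        ``(width, height)`` in pixels of the images used for the 3D
        reconstruction (annotations made at another resolution must be
        rescaled with :func:`scale_annotation_pixel`).
    distortion : (float, float, float)
        Radial coefficients ``(k1, k2, k3)``; all zero means an ideal
        pinhole.
    """

    focal_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]
    distortion: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.focal_px) or self.focal_px <= 0:
            raise ValueError(f"focal_px must be positive and finite, got {self.focal_px}")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        if not np.all(np.isfinite(self.principal_point)):
            raise ValueError(f"principal point must be finite, got {self.principal_point}")
        if len(self.distortion) != 3 or not np.all(np.isfinite(self.distortion)):
            raise ValueError(f"distortion must be three finite radial coefficients, got {self.distortion}")


@dataclass(frozen=True)
class CameraPose:
    """World-to-camera rotation plus optical center, for one image."""

    rotation: np.ndarray
    center: np.ndarray
    image_id: str = ""
    _atol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        C = np.asarray(self.center, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got shape {R.shape}")
        if C.shape != (3,):
            raise ValueError(f"center must be a 3-vector, got shape {C.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(C)):
            raise ValueError(f"non-finite pose for image {self.image_id!r}")
        if not np.allclose(R @ R.T, np.eye(3), atol=self._atol):
            raise ValueError(f"rotation for image {self.image_id!r} is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError(
                f"rotation for image {self.image_id!r} has determinant -1 (reflection)"
            )
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "center", C)


@dataclass(frozen=True)
class Ray:
    """Half-line ``origin + t * direction`` (meters, local frame)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-12:
            raise ValueError(f"ray direction must be unit length, |d| = {n}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


def distort_normalized(xy: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Apply the radial model to normalized coordinates (forward direction)."""
    xy = np.asarray(xy, dtype=float)
    k1, k2, k3 = intrinsics.distortion
    r2 = np.sum(xy * xy, axis=-1, keepdims=True)
    factor = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    return xy * factor


def project_point(
    point_local: np.ndarray, intrinsics: CameraIntrinsics, pose: CameraPose
) -> np.ndarray | None:
    """Project a local-frame 3D point to pixel coordinates.

    Returns ``None`` when the point is on or behind the camera plane
    (``z_c <= 0``).  The result may fall outside the image bounds; it is the
    caller's job to check.
    """
    p = np.asarray(point_local, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError(f"point must be a finite 3-vector, got {point_local!r}")
    xc = pose.rotation @ (p - pose.center)
    if xc[2] <= 0:
        return None
    xy = xc[:2] / xc[2]
    xd = distort_normalized(xy, intrinsics)
    cx, cy = intrinsics.principal_point
    f = intrinsics.focal_px
    return np.array([cx + f * xd[0], cy + f * xd[1]])


def undistort_pixel(
    pixel: tuple[float, float],
    intrinsics: CameraIntrinsics,
    tol: float = 1e-13,
    max_iter: int = 100,
) -> np.ndarray:
    """Invert the radial model: pixel -> ideal normalized coordinates.

    Damped fixed-point iteration starting from the distorted point.  The
    returned ``(x_n, y_n)`` satisfies
    ``|distort(x_n, y_n) - (x_d, y_d)| < tol`` in normalized units and has
    a positive distortion factor (solutions on the folded branch of a
    non-injective model are rejected as non-invertible).
    """
    cx, cy = intrinsics.principal_point
    f = intrinsics.focal_px
    xd = np.array([(pixel[0] - cx) / f, (pixel[1] - cy) / f])
    if not np.all(np.isfinite(xd)):
        raise ValueError(f"pixel must be finite, got {pixel!r}")
    k1, k2, k3 = intrinsics.distortion
    if k1 == k2 == k3 == 0.0:
        return xd
    xn = xd.copy()
    damping = 1.0
    prev_res = np.inf
    for _ in range(max_iter):
        r2 = float(xn @ xn)
        factor = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        residual = np.linalg.norm(xn * factor - xd)
        if residual < tol:
            if factor <= 0:
                raise UndistortionError(
                    f"distortion model is not invertible at pixel {tuple(pixel)} "
                    f"(non-positive radial factor {factor:.3g})"
                )
            return xn
        if residual > prev_res:
            damping *= 0.5  # diverging step: damp towards the previous iterate
        prev_res = residual
        step = xd / factor - xn
        xn = xn + damping * step
    raise UndistortionError(
        f"undistortion did not converge for pixel {tuple(pixel)} "
        f"(residual {prev_res:.3e} after {max_iter} iterations)"
    )


def pixel_to_ray(
    pixel: tuple[float, float], intrinsics: CameraIntrinsics, pose: CameraPose
) -> Ray:
    """Build the world-frame viewing ray through a pixel.

    The ray originates at the camera center and passes through the
    undistorted image point; out-of-bounds pixels are allowed.
    """
    xn = undistort_pixel(pixel, intrinsics)
    d_cam = np.array([xn[0], xn[1], 1.0])
    d_world = pose.rotation.T @ d_cam
    d_world = d_world / np.linalg.norm(d_world)
    return Ray(origin=pose.center, direction=d_world)


def scale_annotation_pixel(
    pixel_annotated: tuple[float, float],
    annotated_size: tuple[float, float],
    intrinsics: CameraIntrinsics,
    aspect_tol: float = 0.005,
) -> np.ndarray:
    """Rescale a pixel from annotated-image to reconstruction resolution.

    Annotations are typically made on full-resolution images while cameras
    are calibrated on downscaled reconstruction images; this maps between
    the two.  The aspect ratios must agree within ``aspect_tol`` (relative),
    otherwise the annotation was very likely paired with the wrong image.
    """
    wa, ha = annotated_size
    if wa <= 0 or ha <= 0:
        raise ValueError(f"annotated size must be positive, got {annotated_size}")
    w, h = intrinsics.image_size
    if abs((wa / ha) - (w / h)) > aspect_tol * (w / h):
        raise ValueError(
            f"aspect ratio mismatch: annotated {wa}x{ha} vs reconstruction {w}x{h} "
            f"(likely wrong image pairing)"
        )
    u, v = pixel_annotated
    return np.array([u * w / wa, v * h / ha])
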