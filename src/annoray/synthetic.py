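"""Synthetic seafloor surveys: terrain, lawnmower trajectory, annotations.

Generates fully specified scenes so the whole pipeline can be exercised
end to end with no external data: a height-field terrain mesh, a
downward-looking camera trajectory flown at constant altitude in parallel
lines (the standard "survey mode" pattern), ground-truth surface features,
and the 2D annotations a perfect annotator would have produced for every
image that sees each feature.

An optional navigation-noise model emulates hybrid (dead-reckoning +
acoustic) vehicle positioning: a slowly wandering drift accumulates with
distance travelled and is periodically reset to the true position plus
acoustic noise.  It is a minimal caricature sufficient to reproduce the
meter-scale mismatch between navigation-based and photogrammetry-based
georeferencing, not a navigation simulator.

Defaults mirror a small deep-sea photo survey: a 24 Mpx-class camera
downscaled for reconstruction (annotations at 2x the reconstruction
resolution), 5 m altitude, 3 m line spacing, 1 m between frames.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .camera import CameraIntrinsics, CameraPose, pixel_to_ray, project_point
from .formats import Annotation2D, CameraView, write_camera_file
from .mesh import BVH, TriangleMesh, build_bvh, intersect_first_hit

logger = logging.getLogger(__name__)

__all__ = [
    "Terrain",
    "Lawnmower",
    "NavNoise",
    "SceneSpec",
    "Scene",
    "default_camera",
    "generate_scene",
    "write_scene",
    "naive_georeference",
]

#: labels cycled over ground-truth features (distinct nearby features with
#: the same label are what duplicate detection must NOT merge)
FEATURE_LABELS = ("madrepora", "actinia", "munidopsis", "ophiuroid")


@dataclass(frozen=True)
class Terrain:
    """Height field z = h(x, y): flat, sinusoidal, or smoothed random field."""

    kind: str = "flat"  # flat | sinusoidal | random_field
    amplitude: float = 0.0  # m
    wavelength: float = 8.0  # m (sinusoidal)
    smoothness: float = 4.0  # smoothing kernel sigma in grid cells (random_field)

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "sinusoidal", "random_field"):
            raise ValueError(f"unknown terrain kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("terrain amplitude must be >= 0")


@dataclass(frozen=True)
class Lawnmower:
    """Parallel-line trajectory at constant altitude, nadir-looking camera."""

    altitude: float = 5.0  # m above z = 0
    line_spacing: float = 3.0  # m between lines
    shot_spacing: float = 1.0  # m between frames along a line

    def __post_init__(self) -> None:
        if min(self.altitude, self.line_spacing, self.shot_spacing) <= 0:
            raise ValueError("lawnmower parameters must be positive")


@dataclass(frozen=True)
class NavNoise:
    """Dead-reckoning drift with periodic acoustic resets."""

    drift_per_m: float = 0.02  # m of position error per m travelled
    reset_interval_m: float = 50.0  # travel distance between resets
    reset_sigma_m: float = 0.05  # std of residual error after a reset

    def __post_init__(self) -> None:
        if self.drift_per_m < 0 or self.reset_interval_m <= 0 or self.reset_sigma_m < 0:
            raise ValueError("invalid nav_noise parameters")


def default_camera() -> CameraIntrinsics:
    """Reconstruction-resolution camera: 2000x1500 px, ~53 deg horizontal FOV."""
    return CameraIntrinsics(
        focal_px=1400.0,
        principal_point=(1000.0, 750.0),
        image_size=(2000, 1500),
        distortion=(-0.05, 0.01, 0.0),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic survey; all randomness flows from ``seed``."""

    terrain: Terrain = field(default_factory=Terrain)
    extent: tuple[float, float] = (30.0, 8.0)  # m
    grid_step: float = 0.25  # m
    trajectory: Lawnmower = field(default_factory=Lawnmower)
    camera: CameraIntrinsics = field(default_factory=default_camera)
    n_features: int = 60
    min_feature_separation: float = 0.5  # m, in the horizontal plane
    annotated_scale: float = 2.0  # annotated resolution / reconstruction resolution
    nav_noise: NavNoise | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if min(self.extent) <= 0:
            raise ValueError("extent must be positive")
        if self.n_features < 0:
            raise ValueError("n_features must be >= 0")
        if self.annotated_scale <= 0:
            raise ValueError("annotated_scale must be positive")
        if self.trajectory.altitude <= self.terrain.amplitude:
            raise ValueError(
                f"altitude {self.trajectory.altitude} m must exceed the terrain "
                f"amplitude {self.terrain.amplitude} m"
            )


@dataclass
class Scene:
    """A generated survey, ready to feed to the pipeline (or to disk)."""

    spec: SceneSpec
    mesh: TriangleMesh
    views: list[CameraView]
    features: list[tuple[str, np.ndarray, str]]  # (feature_id, position, label)
    annotations: list[Annotation2D]
    true_track: np.ndarray  # (n_views, 3) true camera centers
    noisy_track: np.ndarray  # (n_views, 3) hybrid-navigation centers
    annotation_features: dict[str, str] = field(default_factory=dict)  # ann id -> feature id
    bvh: BVH | None = None


def _heights(spec: SceneSpec, x: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t = spec.terrain
    if t.kind == "flat":
        return np.zeros(np.broadcast(x, y).shape)
    if t.kind == "sinusoidal":
        return t.amplitude * np.sin(2 * np.pi * x / t.wavelength) * np.cos(
            2 * np.pi * y / t.wavelength
        )
    noise = rng.standard_normal(np.broadcast(x, y).shape)
    smooth = gaussian_filter(noise, sigma=t.smoothness, mode="wrap")
    peak = np.abs(smooth).max()
    return t.amplitude * smooth / peak if peak > 0 else smooth


def _terrain_mesh(spec: SceneSpec, rng: np.random.Generator) -> TriangleMesh:
    lx, ly = spec.extent
    xs = np.arange(0.0, lx + spec.grid_step / 2, spec.grid_step)
    ys = np.arange(0.0, ly + spec.grid_step / 2, spec.grid_step)
    gx, gy = np.meshgrid(xs, ys)
    gz = _heights(spec, gx, gy, rng)
    nx, ny = len(xs), len(ys)
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriangleMesh(vertices, np.array(faces))


def _lawnmower_centers(spec: SceneSpec) -> np.ndarray:
    lx, ly = spec.extent
    traj = spec.trajectory
    ys = np.arange(traj.line_spacing / 2, ly, traj.line_spacing)
    xs = np.arange(traj.shot_spacing / 2, lx, traj.shot_spacing)
    centers = []
    for k, y in enumerate(ys):
        line = xs if k % 2 == 0 else xs[::-1]  # serpentine
        for x in line:
            centers.append([x, y, traj.altitude])
    return np.array(centers)


# nadir orientation: camera x = +east, camera y (down the image) = -north,
# camera z (viewing direction) = -up; determinant +1
_R_NADIR = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])


def _sample_features(
    spec: SceneSpec, mesh: TriangleMesh, rng: np.random.Generator
) -> list[tuple[str, np.ndarray, str]]:
    """Features sampled uniformly on mesh faces, min-separated in the plane."""
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    prob = areas / areas.sum()
    # keep features away from the border so cameras can actually see them
    margin = 1.0
    lx, ly = spec.extent
    chosen: list[np.ndarray] = []
    max_tries = 200 * max(spec.n_features, 1)
    tries = 0
    while len(chosen) < spec.n_features and tries < max_tries:
        tries += 1
        f = rng.choice(len(areas), p=prob)
        r1, r2 = rng.random(2)
        if r1 + r2 > 1:
            r1, r2 = 1 - r1, 1 - r2
        p = tri[f, 0] + r1 * (tri[f, 1] - tri[f, 0]) + r2 * (tri[f, 2] - tri[f, 0])
        if not (margin <= p[0] <= lx - margin and margin <= p[1] <= ly - margin):
            continue
        if chosen and np.min(
            np.linalg.norm(np.array(chosen)[:, :2] - p[:2], axis=1)
        ) < spec.min_feature_separation:
            continue
        chosen.append(p)
    if len(chosen) < spec.n_features:
        logger.warning(
            "placed only %d of %d features at separation %.2f m",
            len(chosen), spec.n_features, spec.min_feature_separation,
        )
    return [
        (f"F{i:04d}", p, FEATURE_LABELS[i % len(FEATURE_LABELS)])
        for i, p in enumerate(chosen)
    ]


def _noisy_track(
    centers: np.ndarray, noise: NavNoise | None, rng: np.random.Generator
) -> np.ndarray:
    if noise is None or noise.drift_per_m == 0:
        return centers.copy()
    noisy = centers.copy()
    err = np.zeros(2)
    heading = rng.uniform(0, 2 * np.pi)
    since_reset = 0.0
    for i in range(1, len(centers)):
        step = float(np.linalg.norm(centers[i, :2] - centers[i - 1, :2]))
        since_reset += step
        if since_reset >= noise.reset_interval_m:
            err = rng.normal(0.0, noise.reset_sigma_m, 2)
            since_reset = 0.0
        else:
            heading += rng.normal(0.0, 0.3)  # slowly wandering drift direction
            err = err + noise.drift_per_m * step * np.array(
                [np.cos(heading), np.sin(heading)]
            )
        noisy[i, :2] = centers[i, :2] + err
    return noisy


def generate_scene(spec: SceneSpec) -> Scene:
    """Build the full synthetic survey; deterministic for a given spec.

    Every feature is projected into every camera that sees it (in front,
    inside the image bounds, unoccluded per a ray cast against the mesh),
    emitting one Point annotation at annotated resolution per sighting.
    Features visible in no camera are re-placed (a few retries) so the
    survey has no unobservable ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    mesh = _terrain_mesh(spec, rng)
    if mesh.vertices[:, 2].max() >= spec.trajectory.altitude:
        raise ValueError("terrain reaches the flight altitude; raise `altitude`")
    bvh = build_bvh(mesh)
    centers = _lawnmower_centers(spec)
    w, h = spec.camera.image_size
    views = [
        CameraView(
            intrinsics=spec.camera,
            pose=CameraPose(rotation=_R_NADIR, center=c, image_id=f"img_{i:04d}.jpg"),
            image_filename=f"img_{i:04d}.jpg",
        )
        for i, c in enumerate(centers)
    ]
    features = _sample_features(spec, mesh, rng)

    def sightings(pos: np.ndarray) -> list[tuple[CameraView, np.ndarray]]:
        out = []
        for view in views:
            px = project_point(pos, view.intrinsics, view.pose)
            if px is None or not (0.0 <= px[0] <= w and 0.0 <= px[1] <= h):
                continue
            hit = intersect_first_hit(
                pixel_to_ray(px, view.intrinsics, view.pose), mesh, bvh
            )
            if hit is not None and np.linalg.norm(hit.point - pos) < 1e-6:
                out.append((view, px))
        return out

    annotations: list[Annotation2D] = []
    annotation_features: dict[str, str] = {}
    annotated_size = (w * spec.annotated_scale, h * spec.annotated_scale)
    ann_id = 0
    kept_features: list[tuple[str, np.ndarray, str]] = []
    for fid, pos, label in features:
        seen = sightings(pos)
        retries = 0
        while not seen and retries < 5:
            retries += 1
            logger.warning("feature %s visible in no camera; re-placing", fid)
            repl = _sample_features(
                SceneSpec(**{**spec.__dict__, "n_features": 1, "seed": spec.seed + ann_id + retries}),
                mesh,
                np.random.default_rng(spec.seed + 7919 * retries + ann_id),
            )
            if repl:
                pos = repl[0][1]
                seen = sightings(pos)
        kept_features.append((fid, pos, label))
        for view, px in seen:
            ann_id += 1
            annotations.append(
                Annotation2D(
                    annotation_id=str(ann_id),
                    image_filename=view.image_filename,
                    shape="Point",
                    points=np.array(px) * spec.annotated_scale,
                    label=label,
                    annotated_image_size=annotated_size,
                )
            )
            annotation_features[str(ann_id)] = fid
    noisy = _noisy_track(centers, spec.nav_noise, rng)
    return Scene(
        spec=spec,
        mesh=mesh,
        views=views,
        features=kept_features,
        annotations=annotations,
        true_track=centers,
        noisy_track=noisy,
        annotation_features=annotation_features,
        bvh=bvh,
    )


def naive_georeference(
    annotation: Annotation2D,
    noisy_center: np.ndarray,
    intrinsics: CameraIntrinsics,
    altitude: float,
) -> np.ndarray:
    """Hybrid-navigation baseline: flat-projection, altitude-scaled.

    Places an annotation assuming a flat seafloor ``altitude`` meters below
    a nadir camera at the (noisy) navigation position — the conventional
    way image annotations are georeferenced from vehicle navigation.
    """
    px = np.asarray(annotation.points[:2], dtype=float)
    if annotation.annotated_image_size is not None:
        wa, ha = annotation.annotated_image_size
        w, h = intrinsics.image_size
        px = px * np.array([w / wa, h / ha])
    cx, cy = intrinsics.principal_point
    f = intrinsics.focal_px
    dx = (px[0] - cx) / f * altitude
    dy = -(px[1] - cy) / f * altitude  # image v grows south for a nadir camera
    c = np.asarray(noisy_center, dtype=float)
    return np.array([c[0] + dx, c[1] + dy, c[2] - altitude])


def write_scene(scene: Scene, directory: str | os.PathLike) -> dict[str, str]:
    """Write a scene in the exact formats the pipeline consumes.

    ASCII PLY mesh, camera JSON, BIIGLE-style annotation CSV, ground-truth
    feature CSV and the (noisy) navigation track CSV.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    mesh_path = os.path.join(directory, "terrain.ply")
    _write_ascii_ply(scene.mesh, mesh_path)
    paths["mesh"] = mesh_path

    cam_path = os.path.join(directory, "cameras.json")
    write_camera_file(scene.views, cam_path)
    paths["cameras"] = cam_path

    ann_path = os.path.join(directory, "annotations.csv")
    rows = []
    for ann in scene.annotations:
        attrs = ""
        if ann.annotated_image_size is not None:
            attrs = json.dumps(
                {"width": ann.annotated_image_size[0], "height": ann.annotated_image_size[1]}
            )
        rows.append(
            {
                "annotation_id": ann.annotation_id,
                "filename": ann.image_filename,
                "shape_name": ann.shape,
                "points": "[" + ",".join(repr(float(v)) for v in ann.points) + "]",
                "label_name": ann.label,
                "attributes": attrs,
            }
        )
    pd.DataFrame(
        rows,
        columns=["annotation_id", "filename", "shape_name", "points", "label_name", "attributes"],
    ).to_csv(ann_path, index=False)
    paths["annotations"] = ann_path

    gt_path = os.path.join(directory, "ground_truth.csv")
    pd.DataFrame(
        [
            {"feature_id": fid, "x": repr(float(p[0])), "y": repr(float(p[1])),
             "z": repr(float(p[2])), "label": label}
            for fid, p, label in scene.features
        ]
    ).to_csv(gt_path, index=False)
    paths["ground_truth"] = gt_path

    sight_path = os.path.join(directory, "sightings.csv")
    pd.DataFrame(
        [
            {"annotation_id": aid, "feature_id": fid}
            for aid, fid in scene.annotation_features.items()
        ],
        columns=["annotation_id", "feature_id"],
    ).to_csv(sight_path, index=False)
    paths["sightings"] = sight_path

    nav_path = os.path.join(directory, "navigation.csv")
    pd.DataFrame(
        {
            "image_filename": [v.image_filename for v in scene.views],
            "x_true": scene.true_track[:, 0],
            "y_true": scene.true_track[:, 1],
            "z_true": scene.true_track[:, 2],
            "x_nav": scene.noisy_track[:, 0],
            "y_nav": scene.noisy_track[:, 1],
            "z_nav": scene.noisy_track[:, 2],
        }
    ).to_csv(nav_path, index=False)
    paths["navigation"] = nav_path
    return paths


def _write_ascii_ply(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
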