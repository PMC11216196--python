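"""File formats: camera JSON, BIIGLE-style annotation CSV, GeoJSON/CSV outputs.

Camera JSON schema (all field names normative)::

    {
      "intrinsics": {
        "<id>": {"focal": f_px, "cx": ..., "cy": ..., "width": ..., "height": ...,
                 "k1": 0.0, "k2": 0.0, "k3": 0.0}
      },
      "views": {
        "<image filename>": {"intrinsic_id": "<id>",
                             "rotation": [9 numbers, row-major world->camera],
                             "center": [x, y, z]}
      }
    }

A thin adapter converts OpenMVG ``sfm_data.json`` exports to this schema.
Annotation CSVs follow the BIIGLE CSV report dialect (UTF-8, comma
separator, one annotation per row with a bracketed point list).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera import CameraIntrinsics, CameraPose

logger = logging.getLogger(__name__)

__all__ = [
    "Annotation2D",
    "Annotation3D",
    "CameraView",
    "BiigleReadResult",
    "SHAPES",
    "parse_camera_file",
    "write_camera_file",
    "convert_openmvg_sfm",
    "read_biigle_csv",
    "write_outputs",
]

SHAPES = ("Point", "Polygon", "Rectangle", "Circle", "LineString")

_MIN_POINTS = {"Point": 2, "Polygon": 6, "Rectangle": 8, "Circle": 3, "LineString": 4}


@dataclass
class Annotation2D:
    """One labelled 2D annotation on one image, in annotated-image pixels.

    ``points`` is the flat BIIGLE-style list ``[x1, y1, x2, y2, ...]``;
    a Circle is the one odd-length exception, stored as ``[cx, cy, r]``.
    """

    annotation_id: str
    image_filename: str
    shape: str
    points: np.ndarray
    label: str
    annotated_image_size: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).ravel()
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r} (annotation {self.annotation_id})")
        n = len(self.points)
        if self.shape == "Circle":
            if n != 3:
                raise ValueError(f"Circle needs [cx, cy, r], got {n} values")
        else:
            if n < _MIN_POINTS[self.shape] or n % 2 != 0:
                raise ValueError(
                    f"{self.shape} annotation {self.annotation_id} has invalid "
                    f"point count {n}"
                )
            if self.shape == "Point" and n != 2:
                raise ValueError(f"Point must have exactly one vertex, got {n // 2}")

    @property
    def vertices(self) -> np.ndarray:
        """Vertices as an (n, 2) array; for a Circle, the single center."""
        if self.shape == "Circle":
            return self.points[:2].reshape(1, 2)
        return self.points.reshape(-1, 2)


@dataclass
class Annotation3D:
    """A 2D annotation after reprojection onto the terrain mesh.

    ``status`` is ``reprojected`` (all vertices hit the mesh),
    ``partial`` (lenient polygon mode, >= 3 survivors) or ``discarded``
    (a ray missed the mesh; no geometry retained).
    """

    annotation_id: str
    label: str
    status: str
    vertices_local: np.ndarray
    source_image: str
    shape: str = "Point"
    vertices_geo: np.ndarray | None = None  # (n, 3) of lat deg, lon deg, h m
    radius_m: float | None = None  # Circles only

    def __post_init__(self) -> None:
        self.vertices_local = np.asarray(self.vertices_local, dtype=float).reshape(-1, 3)
        if self.status not in ("reprojected", "partial", "discarded"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "discarded" and len(self.vertices_local):
            raise ValueError("discarded annotations must carry no geometry")
        if self.vertices_geo is not None:
            self.vertices_geo = np.asarray(self.vertices_geo, dtype=float).reshape(-1, 3)
            if len(self.vertices_geo) != len(self.vertices_local):
                raise ValueError("local and geodetic vertex lists must have equal length")


@dataclass(frozen=True)
class CameraView:
    """One fully resolved camera: optics + pose + the image it took."""

    intrinsics: CameraIntrinsics
    pose: CameraPose
    image_filename: str


def parse_camera_file(path: str | os.PathLike) -> list[CameraView]:
    """Read the camera JSON schema documented in this module."""
    def _no_dup_keys(pairs):
        d = {}
        for k, v in pairs:
            if k in d:
                raise ValueError(f"duplicate key {k!r} in camera file {path}")
            d[k] = v
        return d

    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh, object_pairs_hook=_no_dup_keys)
    for key in ("intrinsics", "views"):
        if key not in data:
            raise ValueError(f"camera file {path} lacks top-level {key!r}")
    intrinsics: dict[str, CameraIntrinsics] = {}
    for iid, rec in data["intrinsics"].items():
        if "p1" in rec or "p2" in rec or "tangential" in rec:
            raise ValueError(
                f"intrinsic {iid!r}: tangential distortion is not supported "
                "(radial k1/k2/k3 only)"
            )
        intrinsics[str(iid)] = CameraIntrinsics(
            focal_px=float(rec["focal"]),
            principal_point=(float(rec["cx"]), float(rec["cy"])),
            image_size=(int(rec["width"]), int(rec["height"])),
            distortion=(
                float(rec.get("k1", 0.0)),
                float(rec.get("k2", 0.0)),
                float(rec.get("k3", 0.0)),
            ),
        )
    views: list[CameraView] = []
    seen: set[str] = set()
    for filename, rec in data["views"].items():
        if filename in seen:
            raise ValueError(f"duplicate view filename {filename!r}")
        seen.add(filename)
        iid = str(rec["intrinsic_id"])
        if iid not in intrinsics:
            raise ValueError(
                f"view {filename!r} references unknown intrinsic_id {iid!r}"
            )
        rotation = np.asarray(rec["rotation"], dtype=float).reshape(3, 3)
        center = np.asarray(rec["center"], dtype=float)
        try:
            pose = CameraPose(rotation=rotation, center=center, image_id=filename)
        except ValueError as exc:
            raise ValueError(f"view {filename!r}: {exc}") from exc
        views.append(CameraView(intrinsics[iid], pose, filename))
    return views


def write_camera_file(views: list[CameraView], path: str | os.PathLike) -> None:
    """Write cameras in the schema read by :func:`parse_camera_file`."""
    intr_ids: dict[CameraIntrinsics, str] = {}
    intr_out: dict[str, dict] = {}
    views_out: dict[str, dict] = {}
    for view in views:
        intr = view.intrinsics
        if intr not in intr_ids:
            iid = str(len(intr_ids))
            intr_ids[intr] = iid
            intr_out[iid] = {
                "focal": intr.focal_px,
                "cx": intr.principal_point[0],
                "cy": intr.principal_point[1],
                "width": intr.image_size[0],
                "height": intr.image_size[1],
                "k1": intr.distortion[0],
                "k2": intr.distortion[1],
                "k3": intr.distortion[2],
            }
        views_out[view.image_filename] = {
            "intrinsic_id": intr_ids[intr],
            "rotation": [float(x) for x in view.pose.rotation.ravel()],
            "center": [float(x) for x in view.pose.center],
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"intrinsics": intr_out, "views": views_out}, fh, indent=1)


def convert_openmvg_sfm(sfm_path: str | os.PathLike) -> dict:
    """Convert an OpenMVG ``sfm_data.json`` export to the camera JSON schema.

    Only pinhole intrinsics with radial K3 distortion are supported; views
    without a reconstructed pose are dropped.  Returns the schema dict
    (pass it to ``json.dump`` or feed to :func:`parse_camera_file` via a
    temp file).
    """
    with open(sfm_path, "r", encoding="utf-8") as fh:
        sfm = json.load(fh)
    intr_out: dict[str, dict] = {}
    for rec in sfm.get("intrinsics", []):
        key = str(rec["key"])
        val = rec["value"]["ptr_wrapper"]["data"]
        disto = val.get("disto_k3", [0.0, 0.0, 0.0])
        intr_out[key] = {
            "focal": float(val["focal_length"]),
            "cx": float(val["principal_point"][0]),
            "cy": float(val["principal_point"][1]),
            "width": int(val["width"]),
            "height": int(val["height"]),
            "k1": float(disto[0]),
            "k2": float(disto[1]),
            "k3": float(disto[2]),
        }
    poses = {str(rec["key"]): rec["value"] for rec in sfm.get("extrinsics", [])}
    views_out: dict[str, dict] = {}
    for rec in sfm.get("views", []):
        val = rec["value"]["ptr_wrapper"]["data"]
        pose_id = str(val.get("id_pose", ""))
        if pose_id not in poses:
            continue
        pose = poses[pose_id]
        rotation = np.asarray(pose["rotation"], dtype=float).reshape(9)
        views_out[val["filename"]] = {
            "intrinsic_id": str(val["id_intrinsic"]),
            "rotation": [float(x) for x in rotation],
            "center": [float(x) for x in pose["center"]],
        }
    return {"intrinsics": intr_out, "views": views_out}


@dataclass
class BiigleReadResult:
    """Annotations parsed from a BIIGLE CSV report, plus row accounting.

    The invariant ``n_rows == len(annotations) + n_skipped`` always holds.
    """

    annotations: list[Annotation2D]
    n_rows: int
    n_skipped: int
    skipped_reasons: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)


_COLUMN_SYNONYMS = {
    "annotation_id": ("annotation_id", "id"),
    "filename": ("filename", "image_filename"),
    "shape_name": ("shape_name", "shape"),
    "points": ("points",),
    "label_name": ("label_name", "label"),
}


def read_biigle_csv(path: str | os.PathLike) -> BiigleReadResult:
    """Parse a BIIGLE-style CSV annotation report.

    Rows with unknown shape names or unparseable point lists are skipped
    with a logged warning and counted, never silently dropped.  An
    ``attributes`` column, if present, may carry the annotated image size
    as JSON ``{"width": ..., "height": ...}``.
    """
    df = pd.read_csv(path)
    cols: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for canon, synonyms in _COLUMN_SYNONYMS.items():
        for syn in synonyms:
            if syn in lower:
                cols[canon] = lower[syn]
                break
        else:
            raise ValueError(
                f"{path}: missing required column {canon!r} "
                f"(accepted names {synonyms}); found columns {list(df.columns)}"
            )
    attr_col = lower.get("attributes")
    annotations: list[Annotation2D] = []
    skipped: list[str] = []
    for idx, row in df.iterrows():
        shape = str(row[cols["shape_name"]])
        try:
            pts = json.loads(str(row[cols["points"]]))
            pts = np.asarray(pts, dtype=float).ravel()
            size = None
            if attr_col is not None and isinstance(row[attr_col], str):
                attrs = json.loads(row[attr_col])
                if "width" in attrs and "height" in attrs:
                    size = (float(attrs["width"]), float(attrs["height"]))
            ann = Annotation2D(
                annotation_id=str(row[cols["annotation_id"]]),
                image_filename=str(row[cols["filename"]]),
                shape=shape,
                points=pts,
                label=str(row[cols["label_name"]]),
                annotated_image_size=size,
            )
        except (ValueError, json.JSONDecodeError) as exc:
            reason = f"row {idx}: {exc}"
            skipped.append(reason)
            logger.warning("skipping annotation %s", reason)
            continue
        annotations.append(ann)
    return BiigleReadResult(
        annotations=annotations,
        n_rows=len(df),
        n_skipped=len(skipped),
        skipped_reasons=skipped,
    )


def _geojson_geometry(ann: Annotation3D) -> dict | None:
    if ann.vertices_geo is None or len(ann.vertices_geo) == 0:
        return None
    # GeoJSON wants [lon, lat, height] (RFC 7946)
    coords = [[float(lon), float(lat), float(h)] for lat, lon, h in ann.vertices_geo]
    if ann.shape in ("Point", "Circle") or len(coords) == 1:
        return {"type": "Point", "coordinates": coords[0]}
    if ann.shape == "LineString":
        return {"type": "LineString", "coordinates": coords}
    ring = coords + [coords[0]]
    return {"type": "Polygon", "coordinates": [ring]}


def write_outputs(
    annotations: list[Annotation3D],
    footprints: list | None,
    path_prefix: str | os.PathLike,
) -> dict[str, str]:
    """Write reprojected annotations (and optional footprints) to disk.

    Produces ``<prefix>_annotations.geojson`` (reprojected/partial only)
    and a flat CSV twin ``<prefix>_annotations.csv`` that also lists
    discarded annotations with empty geometry; footprints, when given, go
    to ``<prefix>_footprints.geojson``.  Returns the paths written.
    """
    prefix = os.fspath(path_prefix)
    written: dict[str, str] = {}

    features = []
    for ann in annotations:
        geom = _geojson_geometry(ann)
        if geom is None:
            continue
        props = {
            "annotation_id": ann.annotation_id,
            "label": ann.label,
            "status": ann.status,
            "source_image": ann.source_image,
        }
        if ann.radius_m is not None:
            props["radius_m"] = float(ann.radius_m)
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    geojson_path = prefix + "_annotations.geojson"
    with open(geojson_path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    written["annotations_geojson"] = geojson_path

    rows = []
    for ann in annotations:
        if len(ann.vertices_local) == 0:
            rows.append(
                {
                    "annotation_id": ann.annotation_id,
                    "vertex_index": "",
                    "label": ann.label,
                    "status": ann.status,
                    "source_image": ann.source_image,
                    "x_local": "", "y_local": "", "z_local": "",
                    "lat": "", "lon": "", "height": "",
                }
            )
            continue
        geo = ann.vertices_geo
        for i, p in enumerate(ann.vertices_local):
            rows.append(
                {
                    "annotation_id": ann.annotation_id,
                    "vertex_index": i,
                    "label": ann.label,
                    "status": ann.status,
                    "source_image": ann.source_image,
                    "x_local": repr(float(p[0])),
                    "y_local": repr(float(p[1])),
                    "z_local": repr(float(p[2])),
                    "lat": repr(float(geo[i][0])) if geo is not None else "",
                    "lon": repr(float(geo[i][1])) if geo is not None else "",
                    "height": repr(float(geo[i][2])) if geo is not None else "",
                }
            )
    csv_path = prefix + "_annotations.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    written["annotations_csv"] = csv_path

    if footprints is not None:
        fp_features = []
        for fp in footprints:
            if fp.status == "discarded" or len(fp.vertices_local) < 3:
                continue
            geo = getattr(fp, "vertices_geo", None)
            if geo is not None:
                coords = [[float(lon), float(lat), float(h)] for lat, lon, h in geo]
            else:
                coords = [[float(x), float(y), float(z)] for x, y, z in fp.vertices_local]
            ring = coords + [coords[0]]
            fp_features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "image_filename": fp.image_filename,
                        "status": fp.status,
                        "crs": "WGS84" if geo is not None else "local",
                    },
                }
            )
        fp_path = prefix + "_footprints.geojson"
        with open(fp_path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": fp_features}, fh)
        written["footprints_geojson"] = fp_path
    return written
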