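"""Reprojection engine: vertex casting, polygon handling, footprints, locate-back."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon

from annoray import (
    Annotation2D,
    CameraIntrinsics,
    CameraPose,
    CameraView,
    GeoAnchor,
    TriangleMesh,
    build_bvh,
    compute_footprint,
    generate_scene,
    georeference_annotations,
    locate_in_images,
    reproject_all,
    reproject_annotation,
    reproject_vertex,
    SceneSpec,
    Terrain,
)
from annoray.engine import _boundary_pixels

from conftest import R_NADIR, brute_force_first_hit


@pytest.fixture
def nadir_view(nadir_intrinsics, nadir_pose) -> CameraView:
    return CameraView(nadir_intrinsics, nadir_pose, "nadir.jpg")


@pytest.fixture
def holed_mesh():
    """Two squares with a 2 m gap between them (a modelling hole)."""
    v = []
    f = []
    for k, x0 in enumerate([-10.0, 2.0]):  # squares [x0, x0+8] x [-10, 10]
        v += [[x0, -10, 0], [x0 + 8, -10, 0], [x0 + 8, 10, 0], [x0, 10, 0]]
        f += [[4 * k, 4 * k + 1, 4 * k + 2], [4 * k, 4 * k + 2, 4 * k + 3]]
    mesh = TriangleMesh(np.array(v, float), np.array(f))
    return mesh, build_bvh(mesh)


class TestReprojectVertex:
    def test_optical_axis_hits_directly_below(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        p = reproject_vertex((500.0, 500.0), nadir_view.intrinsics, nadir_view.pose, mesh, bvh)
        assert np.allclose(p, (0.0, 0.0, 0.0), atol=1e-12)

    def test_100px_offset_is_one_meter(self, nadir_view, plane_mesh):
        # 100 px / 1000 px focal * 10 m altitude = 1 m
        mesh, bvh = plane_mesh
        p = reproject_vertex((600.0, 500.0), nadir_view.intrinsics, nadir_view.pose, mesh, bvh)
        assert np.allclose(p, (1.0, 0.0, 0.0), atol=1e-9)

    def test_matches_brute_force_on_sinusoidal_terrain(self):
        scene = generate_scene(
            SceneSpec(
                terrain=Terrain("sinusoidal", amplitude=0.4),
                extent=(8.0, 6.0),
                n_features=0,
                seed=3,
            )
        )
        view = scene.views[len(scene.views) // 2]
        rng = np.random.default_rng(1)
        for px in rng.uniform([400, 300], [1600, 1200], size=(25, 2)):
            ours = reproject_vertex(px, view.intrinsics, view.pose, scene.mesh, scene.bvh)
            from annoray import pixel_to_ray

            ray = pixel_to_ray(px, view.intrinsics, view.pose)
            ref = brute_force_first_hit(ray.origin, ray.direction, scene.mesh)
            if ref is None:
                assert ours is None
            else:
                assert np.abs(ours - ray.at(ref[1])).max() < 1e-9


class TestReprojectAnnotation:
    def test_point_over_terrain_reprojects(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        ann = Annotation2D("1", "nadir.jpg", "Point", [500.0, 500.0], "coral")
        out = reproject_annotation(ann, nadir_view, mesh, bvh)
        assert out.status == "reprojected"
        assert out.vertices_local.shape == (1, 3)

    def test_ray_past_mesh_boundary_discards(self, nadir_view):
        small = TriangleMesh(
            np.array([[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0]], float),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        bvh = build_bvh(small)
        ann = Annotation2D("1", "nadir.jpg", "Point", [950.0, 500.0], "coral")
        out = reproject_annotation(ann, nadir_view, small, bvh)
        assert out.status == "discarded"
        assert len(out.vertices_local) == 0

    def test_polygon_with_hole_strict_vs_lenient(self, nadir_view, holed_mesh):
        mesh, bvh = holed_mesh
        # pixels at x offsets -4, -3, +4 m map down fine; x = +1 m is over the gap
        def px(x_m):
            return 500.0 + 100.0 * x_m  # f/alt = 1000/10 = 100 px per meter

        pts = [px(-4), 400.0, px(-3), 600.0, px(1), 500.0, px(4), 500.0]
        ann = Annotation2D("7", "nadir.jpg", "Polygon", pts, "patch")
        strict = reproject_annotation(ann, nadir_view, mesh, bvh, mode="strict")
        assert strict.status == "discarded"
        lenient = reproject_annotation(ann, nadir_view, mesh, bvh, mode="lenient")
        assert lenient.status == "partial"
        assert len(lenient.vertices_local) == 3

    def test_lenient_below_three_survivors_discards(self, nadir_view, holed_mesh):
        mesh, bvh = holed_mesh
        pts = [500 + 100 * 1, 500, 500 + 100 * 1.2, 500, 500 - 100 * 3, 500]
        ann = Annotation2D("8", "nadir.jpg", "Polygon", pts, "patch")
        out = reproject_annotation(ann, nadir_view, mesh, bvh, mode="lenient")
        assert out.status == "discarded"

    def test_circle_center_and_radius(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        ann = Annotation2D("9", "nadir.jpg", "Circle", [500.0, 500.0, 100.0], "ring")
        out = reproject_annotation(ann, nadir_view, mesh, bvh)
        assert out.status == "reprojected"
        assert np.allclose(out.vertices_local[0], (0, 0, 0), atol=1e-9)
        assert np.isclose(out.radius_m, 1.0, atol=1e-9)  # 100 px at 100 px/m

    def test_annotated_resolution_rescaling(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        # annotated at 2x: pixel (1200, 1000) -> reconstruction (600, 500) -> (1, 0, 0)
        ann = Annotation2D(
            "2", "nadir.jpg", "Point", [1200.0, 1000.0], "coral",
            annotated_image_size=(2000.0, 2000.0),
        )
        out = reproject_annotation(ann, nadir_view, mesh, bvh)
        assert np.allclose(out.vertices_local[0], (1.0, 0.0, 0.0), atol=1e-9)

    def test_conservation_and_missing_camera(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        anns = [
            Annotation2D(str(i), "nadir.jpg", "Point", [500.0 + 10 * i, 500.0], "c")
            for i in range(5)
        ]
        out = reproject_all(anns, [nadir_view], mesh, bvh)
        counts = {s: sum(a.status == s for a in out) for s in ("reprojected", "partial", "discarded")}
        assert sum(counts.values()) == len(anns)
        with pytest.raises(ValueError, match="other.jpg"):
            reproject_all(
                [Annotation2D("9", "other.jpg", "Point", [1.0, 1.0], "c")],
                [nadir_view], mesh, bvh,
            )

    def test_georeferencing_fills_geo_vertices(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        ann = Annotation2D("1", "nadir.jpg", "Point", [500.0, 500.0], "coral")
        out = [reproject_annotation(ann, nadir_view, mesh, bvh)]
        georeference_annotations(out, GeoAnchor(47.61116, -7.53664, -800.0))
        assert out[0].vertices_geo.shape == (1, 3)
        assert abs(out[0].vertices_geo[0][0] - 47.61116) < 1e-5


class TestFootprint:
    def test_closed_form_square_footprint(self, nadir_view, plane_mesh):
        # half-extent = altitude * (width/2) / f = 10 * 500 / 1000 = 5 m
        mesh, bvh = plane_mesh
        fp = compute_footprint(nadir_view, mesh, bvh, densify_n=0)
        assert fp.status == "complete"
        expected = {(-5.0, 5.0), (5.0, 5.0), (5.0, -5.0), (-5.0, -5.0)}
        got = {(round(x, 9), round(y, 9)) for x, y, _ in fp.vertices_local}
        assert got == expected
        assert np.abs(fp.vertices_local[:, 2]).max() < 1e-9

    def test_corner_order_follows_image_boundary(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        fp = compute_footprint(nadir_view, mesh, bvh)
        # image TL (0,0) maps to (-x, +y) on the ground for a nadir camera
        assert np.allclose(fp.vertices_local[0][:2], (-5.0, 5.0), atol=1e-9)
        assert np.allclose(fp.vertices_local[1][:2], (5.0, 5.0), atol=1e-9)

    def test_skyward_camera_is_discarded(self, nadir_intrinsics, plane_mesh):
        mesh, bvh = plane_mesh
        up = CameraPose(rotation=np.eye(3), center=np.array([0.0, 0.0, 10.0]))
        fp = compute_footprint(CameraView(nadir_intrinsics, up, "sky.jpg"), mesh, bvh)
        assert fp.status == "discarded" and len(fp.vertices_local) == 0

    def test_densified_footprint_lies_on_rough_terrain(self):
        scene = generate_scene(
            SceneSpec(
                terrain=Terrain("random_field", amplitude=0.6, smoothness=3.0),
                extent=(10.0, 8.0),
                n_features=0,
                seed=5,
            )
        )
        view = scene.views[len(scene.views) // 2]
        fp = compute_footprint(view, scene.mesh, scene.bvh, densify_n=10)
        assert fp.status == "complete"
        assert len(fp.vertices_local) == 4 * (10 + 1)
        # every vertex must sit on the mesh: re-hit through brute force
        for vtx in fp.vertices_local:
            d = vtx - view.pose.center
            t = np.linalg.norm(d)
            ref = brute_force_first_hit(view.pose.center, d / t, scene.mesh)
            assert ref is not None and abs(ref[1] - t) < 1e-6

    def test_boundary_pixel_layout(self):
        pts = _boundary_pixels(100.0, 50.0, 2)
        assert len(pts) == 4 * 3
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[3]) == (100.0, 0.0)

    def test_annotations_fall_inside_their_footprint(self):
        """Horizontal-plane containment of reprojected points in the footprint."""
        scene = generate_scene(
            SceneSpec(
                terrain=Terrain("sinusoidal", amplitude=0.3),
                extent=(16.0, 12.0),
                n_features=15,
                seed=9,
            )
        )
        by_image: dict[str, list] = {}
        for ann in scene.annotations:
            by_image.setdefault(ann.image_filename, []).append(ann)
        views = {v.image_filename: v for v in scene.views}
        ann3d = reproject_all(scene.annotations, scene.views, scene.mesh, scene.bvh)
        fp_cache = {}
        checked = 0
        for ann2d, ann3 in zip(scene.annotations, ann3d):
            if ann3.status != "reprojected":
                continue
            img = ann2d.image_filename
            if img not in fp_cache:
                fp_cache[img] = compute_footprint(views[img], scene.mesh, scene.bvh, densify_n=5)
            fp = fp_cache[img]
            if fp.status != "complete":
                continue
            poly = ShapelyPolygon(fp.vertices_local[:, :2]).buffer(1e-3)
            assert poly.contains(ShapelyPoint(ann3.vertices_local[0][:2]))
            checked += 1
        assert checked > 10


class TestLocateInImages:
    def test_point_below_nadir_camera_is_visible_at_center(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        res = locate_in_images(np.zeros(3), [nadir_view], mesh, bvh)
        assert len(res) == 1
        assert res[0].visible
        assert np.allclose(res[0].pixel, (500.0, 500.0), atol=1e-9)

    def test_occluded_point_is_candidate_but_not_visible(self, nadir_view):
        # ground plane plus a small shelf at z = 1 straight under the camera
        v = [[-20, -20, 0], [20, -20, 0], [20, 20, 0], [-20, 20, 0],
             [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]]
        f = [[0, 1, 2], [0, 2, 3], [4, 5, 6], [4, 6, 7]]
        mesh = TriangleMesh(np.array(v, float), np.array(f))
        bvh = build_bvh(mesh)
        res = locate_in_images(np.zeros(3), [nadir_view], mesh, bvh)
        assert len(res) == 1
        assert not res[0].visible  # the shelf intercepts the ray at z = 1

    def test_point_outside_fov_yields_no_candidate(self, nadir_view, plane_mesh):
        mesh, bvh = plane_mesh
        res = locate_in_images(np.array([50.0, 0.0, 0.0]), [nadir_view], mesh, bvh)
        assert res == []

    def test_synthetic_features_visible_at_annotation_pixel(self):
        scene = generate_scene(
            SceneSpec(terrain=Terrain("sinusoidal", amplitude=0.3),
                      extent=(10.0, 6.0), n_features=10, seed=21)
        )
        feat_pos = {fid: p for fid, p, _ in scene.features}
        views = {v.image_filename: v for v in scene.views}
        checked = 0
        for ann in scene.annotations[:40]:
            fid = scene.annotation_features[ann.annotation_id]
            res = locate_in_images(feat_pos[fid], list(views.values()), scene.mesh, scene.bvh)
            mine = [r for r in res if r.image_filename == ann.image_filename]
            assert len(mine) == 1 and mine[0].visible
            recon_px = ann.points[:2] / scene.spec.annotated_scale
            assert np.abs(mine[0].pixel - recon_px).max() < 0.5
            checked += 1
        assert checked > 0
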