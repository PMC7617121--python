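"""Convex-hull measurement operations: Prague C&M, islands, areas, categories."""

import math

import numpy as np
import pytest

from barrettometry.masks import SegMasks
from barrettometry.phantom import CameraModel, Pose, render_frame
from barrettometry.quantification import (
    fit_convex_hull,
    junction_center,
    extrema_distances,
    measure_area,
    measure_frame,
    measure_island_diameter,
    measure_prague,
    to_prague_category,
)


def _point_in_polygon(point, verts):
    """Independent ray-casting point-in-polygon oracle ((row, col) verts)."""
    y, x = point
    inside = False
    n = len(verts)
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin + 1e-9:
                inside = not inside
    return inside


class TestConvexHull:
    def test_filled_square_has_corner_vertices(self):
        m = np.zeros((64, 64), bool)
        m[10:31, 20:41] = True
        hull = fit_convex_hull(m)
        corners = {(10, 20), (10, 40), (30, 20), (30, 40)}
        assert {tuple(map(int, v)) for v in hull.vertices} == corners

    def test_every_masked_pixel_inside_hull(self):
        rng = np.random.default_rng(4)
        m = np.zeros((48, 48), bool)
        pts = rng.integers(5, 43, (60, 2))
        m[pts[:, 0], pts[:, 1]] = True
        hull = fit_convex_hull(m)
        for p in np.argwhere(m):
            assert hull.contains(p[None, :])[0] or _point_in_polygon(
                p + 0.0, hull.vertices
            ) or any(np.array_equal(p, v.astype(int)) for v in hull.vertices)

    def test_hull_of_hull_vertices_is_same_hull(self):
        m = np.zeros((64, 64), bool)
        m[5:40, 10:50] = True
        hull = fit_convex_hull(m)
        m2 = np.zeros((64, 64), bool)
        for v in hull.vertices.astype(int):
            m2[v[0], v[1]] = True
        hull2 = fit_convex_hull(m2)
        assert np.allclose(np.sort(hull.vertices, axis=0),
                           np.sort(hull2.vertices, axis=0))

    def test_degenerate_masks_rejected(self):
        m = np.zeros((16, 16), bool)
        m[3, 3] = m[3, 8] = True
        with pytest.raises(ValueError):
            fit_convex_hull(m)
        m[3, 12] = True  # three collinear pixels
        with pytest.raises(ValueError):
            fit_convex_hull(m)


class TestJunctionCenter:
    def test_centered_disk(self):
        m = np.zeros((256, 256), bool)
        rr, cc = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
        m[(rr - 128) ** 2 + (cc - 128) ** 2 < 400] = True
        assert junction_center(m) == ((128, 128), False)

    def test_two_pixel_mask(self):
        m = np.zeros((8, 8), bool)
        m[0, 0] = m[0, 2] = True
        assert junction_center(m)[0] == (0, 1)

    def test_annulus_relocates_to_nearest_valid(self):
        m = np.zeros((64, 64), bool)
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        d2 = (rr - 32) ** 2 + (cc - 32) ** 2
        m[(d2 >= 100) & (d2 <= 196)] = True  # annulus, centroid in the hole
        valid = m.copy()
        center, relocated = junction_center(m, valid)
        assert relocated
        # oracle: exhaustive nearest valid pixel to the true centroid
        centroid = np.argwhere(m).mean(axis=0)
        vpix = np.argwhere(valid)
        best = vpix[np.argmin(((vpix - centroid) ** 2).sum(axis=1))]
        assert np.linalg.norm(np.array(center) - centroid) <= \
            np.linalg.norm(best - centroid) + 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            junction_center(np.zeros((8, 8), bool))


class TestExtremaDistances:
    def test_plane_geodesic_equals_scaled_pixel_distance(self, camera):
        depth = np.full((256, 256), 64.0)
        m = np.zeros((256, 256), bool)
        m[96:161, 96:161] = True
        hull = fit_convex_hull(m)
        center = (128, 128)
        dists, skipped = extrema_distances(center, hull, depth, camera)
        assert not skipped
        for vertex, d in dists:
            px = np.linalg.norm(np.asarray(vertex) - center)
            # rasterized 8-connected path: diagonal+straight decomposition
            dr, dc = abs(vertex[0] - 128), abs(vertex[1] - 128)
            raster_len = (min(dr, dc) * math.sqrt(2) + abs(dr - dc))
            assert d == pytest.approx(raster_len * 64.0 / 128.0, rel=1e-9)
            assert d >= px * 64.0 / 128.0 - 1e-9


class TestMeasurePrague:
    def test_no_barretts_gives_zero(self, camera):
        masks = SegMasks(bea=np.zeros((32, 32), bool),
                         junction=np.ones((32, 32), bool),
                         valid=np.ones((32, 32), bool))
        c, m, _ = measure_prague(masks, np.full((32, 32), 10.0), camera)
        assert (c, m) == (0.0, 0.0)

    def test_c_never_exceeds_m_across_dataset(self, band_phantom, camera):
        from barrettometry.phantom import sample_trajectory

        poses = sample_trajectory("spiral", 6, (1, 20), (1, 10), "forward", 5,
                                  tube_length=100.0, z_range=(3.0, 8.0))
        junction = None
        for pose in poses:
            frame = render_frame(band_phantom, pose, camera)
            masks = frame.gt_masks
            if not masks.junction.any():
                # band phantom has no painted junction; use the distal band edge
                masks = SegMasks(bea=masks.bea, islands=masks.islands,
                                 junction=masks.bea & (frame.depth >
                                                       np.percentile(
                                                           frame.depth[masks.bea],
                                                           95)),
                                 valid=masks.valid)
            c, m, _ = measure_prague(masks, frame.depth, camera)
            assert c <= m + 1e-9

    def test_length_markers_recovered_within_5pct(self, length_experiment):
        rel = length_experiment.report.relative_error_pct
        assert np.all(rel <= 5.0)


class TestIslandDiameter:
    def test_single_pixel_island_is_zero(self, camera):
        m = np.zeros((32, 32), bool)
        m[5, 5] = True
        assert measure_island_diameter(m, np.full((32, 32), 20.0), camera) == 0.0

    def test_empty_island_rejected(self, camera):
        with pytest.raises(ValueError):
            measure_island_diameter(np.zeros((8, 8), bool),
                                    np.full((8, 8), 5.0), camera)

    def test_plane_disk_diameter(self, camera):
        depth = np.full((256, 256), 128.0)  # 1 px = 1 mm
        m = np.zeros((256, 256), bool)
        rr, cc = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
        m[(rr - 128) ** 2 + (cc - 128) ** 2 <= 30 ** 2] = True
        d = measure_island_diameter(m, depth, camera)
        assert d == pytest.approx(60.0, rel=0.03)

    def test_diameter_bounds_any_pairwise_extent(self, camera):
        depth = np.full((64, 64), 64.0)
        m = np.zeros((64, 64), bool)
        m[20:40, 10:50] = True
        d = measure_island_diameter(m, depth, camera)
        # the diameter is at least the rectangle diagonal in mm
        diag_mm = math.hypot(19, 39) * 0.5
        assert d >= diag_mm - 1e-6


class TestMeasureArea:
    def test_small_fold_area_not_subtracted(self, camera):
        depth = np.full((256, 256), 40.0)  # px footprint (40/128)^2 mm^2
        bea = np.zeros((256, 256), bool)
        bea[50:150, 50:150] = True
        junction = np.zeros((256, 256), bool)
        junction[160:180, 50:80] = True  # ~0.6 cm^2 < 1 cm^2 threshold
        masks = SegMasks(bea=bea, junction=junction,
                         valid=np.ones((256, 256), bool))
        a_b, a_fold, bea_area, _ = measure_area(masks, depth, camera)
        assert a_fold < 1.0
        assert bea_area == a_b

    def test_large_fold_area_subtracted(self, camera):
        depth = np.full((256, 256), 60.0)
        bea = np.zeros((256, 256), bool)
        bea[40:200, 40:200] = True
        junction = np.zeros((256, 256), bool)
        junction[90:150, 90:150] = True  # inside the hull, > 1 cm^2
        bea[90:150, 90:150] = False
        masks = SegMasks(bea=bea, junction=junction,
                         valid=np.ones((256, 256), bool))
        a_b, a_fold, bea_area, _ = measure_area(masks, depth, camera)
        assert a_fold > 1.0
        assert bea_area == pytest.approx(a_b - a_fold)

    def test_empty_masks_all_zero(self, camera):
        masks = SegMasks(bea=np.zeros((16, 16), bool))
        assert measure_area(masks, np.full((16, 16), 5.0), camera) == \
            (0.0, 0.0, 0.0, [])

    def test_area_markers_recovered_within_3pct(self, area_experiment):
        assert np.all(area_experiment.report.relative_error_pct <= 3.0)


class TestPragueCategories:
    @pytest.mark.parametrize(
        "length_cm,label",
        [(2.31, "1-3"), (0.0, "0-1"), (3.0, "3-5"), (0.99, "0-1"),
         (7.0, "7-9"), (11.0, ">11"), (25.0, ">11")],
    )
    def test_binning(self, length_cm, label):
        assert to_prague_category(length_cm) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            to_prague_category(-0.1)


class TestMeasureFrame:
    def test_frame_without_junction_sets_flag(self, band_frame, camera):
        m = measure_frame(band_frame, camera, use_gt_masks=True)
        # the plain band phantom paints no junction landmark
        assert "junction_not_visible" in m.quality_flags
        assert m.C == 0.0 and m.M == 0.0
        assert m.A_b > 0  # areas do not need the junction center

    def test_unpainted_phantom_measures_nothing(self, camera):
        from barrettometry.phantom import build_phantom

        phantom = build_phantom(100.0, 20.0, [])
        frame = render_frame(phantom, Pose(np.eye(3), np.array([0, 0, 5.0])),
                             camera)
        m = measure_frame(frame, camera)
        assert "no_barretts" in m.quality_flags
        assert m.C == m.M == m.A_b == m.BEA == 0.0

    def test_invariant_to_90deg_image_rotation(self):
        """Rotating all inputs by 90 deg must not change the measurements."""
        from barrettometry.experiments import (
            MEASUREMENT_CAMERA,
            _measurement_poses,
            build_length_phantom,
        )
        from barrettometry.phantom import Frame

        rng = np.random.default_rng(0)
        phantom = build_length_phantom()
        pose = _measurement_poses(rng, 1, phantom.z_folds - 95.0)[0]
        frame = render_frame(phantom, pose, MEASUREMENT_CAMERA)
        m0 = measure_frame(frame, MEASUREMENT_CAMERA)

        rot = lambda a: np.rot90(a).copy()
        masks = frame.gt_masks
        rmasks = SegMasks(bea=rot(masks.bea),
                          islands=[rot(i) for i in masks.islands],
                          junction=rot(masks.junction), valid=rot(masks.valid))
        rframe = Frame(rgb=rot(frame.rgb), depth=rot(frame.depth),
                       pose=pose, gt_masks=rmasks)
        m1 = measure_frame(rframe, MEASUREMENT_CAMERA)
        assert m1.C == pytest.approx(m0.C, rel=0.01)
        assert m1.M == pytest.approx(m0.M, rel=0.01)
        assert m1.A_b == pytest.approx(m0.A_b, rel=0.01)
        for d0, d1 in zip(sorted(m0.island_diameters),
                          sorted(m1.island_diameters)):
            assert d1 == pytest.approx(d0, rel=0.01)
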