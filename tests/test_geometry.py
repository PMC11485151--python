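import numpy as np
import pytest

from tractoshape.geometry import (
    PointCloud,
    arc_length,
    discrete_curvature,
    extract_centroid,
    resample_polyline,
)
from tractoshape.io_streamlines import BundleSet
from tractoshape.shape_distance import pairwise_distance


class TestResample:
    @pytest.mark.parametrize(
        "points, n, expected",
        [
            # straight segment: uniform x spacing
            ([(0, 0, 0), (10, 0, 0)], 5, [(0, 0, 0), (2.5, 0, 0), (5, 0, 0), (7.5, 0, 0), (10, 0, 0)]),
            # n=2 returns the endpoints of any polyline
            ([(0, 0, 0), (3, 0, 0), (3, 4, 0)], 2, [(0, 0, 0), (3, 4, 0)]),
            # arc-length midpoint of an equal-armed corner is the corner itself
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0)], 3, [(0, 0, 0), (1, 0, 0), (1, 1, 0)]),
        ],
    )
    def test_known_resamplings(self, points, n, expected):
        out = resample_polyline(np.array(points, float), n)
        np.testing.assert_allclose(out.points, np.array(expected, float), atol=1e-12)

    def test_points_sit_at_uniform_arc_length_fractions(self, rng):
        def point_at_arc_length(pts, s):
            # independent oracle: walk the segments until s is consumed
            for a, b in zip(pts[:-1], pts[1:]):
                seg = np.linalg.norm(b - a)
                if s <= seg:
                    return a + (b - a) * (s / seg)
                s -= seg
            return pts[-1]

        pts = np.cumsum(rng.normal(0, 1, size=(30, 3)), axis=0)
        out = resample_polyline(pts, 17)
        total = arc_length(pts)
        for i, p in enumerate(out.points):
            expected = point_at_arc_length(pts, total * i / 16)
            np.testing.assert_allclose(p, expected, atol=1e-9)
        np.testing.assert_array_equal(out.points[0], pts[0])
        np.testing.assert_array_equal(out.points[-1], pts[-1])

    def test_arc_length_converges_monotonically_on_smooth_curve(self):
        t = np.linspace(0, np.pi, 400)
        semicircle = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 0 * t])
        target = arc_length(semicircle)
        lengths = [arc_length(resample_polyline(semicircle, n)) for n in (8, 16, 32, 64)]
        assert all(a < b for a, b in zip(lengths, lengths[1:]))
        assert abs(lengths[-1] - target) < abs(lengths[0] - target)

    def test_zero_length_streamline_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_polyline(np.zeros((2, 3)), 5)


class TestArcLength:
    def test_straight_and_square(self):
        assert arc_length(np.array([[0, 0, 0], [10, 0, 0]], float)) == 10.0
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]], float)
        assert arc_length(square) == pytest.approx(4.0)

    def test_semicircle_dense_sampling_near_analytic(self):
        t = np.linspace(0, np.pi, 64)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 0 * t])
        assert arc_length(pts) == pytest.approx(10 * np.pi, rel=5e-3)


class TestCurvature:
    def test_straight_line_turns_zero(self):
        pts = np.column_stack([np.linspace(0, 10, 9), np.zeros(9), np.zeros(9)])
        total, per_mm = discrete_curvature(pts)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert per_mm == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("radius", [1.0, 10.0, 250.0])
    def test_semicircle_turning_radius_free(self, radius):
        t = np.linspace(0, np.pi, 41)
        pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), 0 * t])
        total, _ = discrete_curvature(pts)
        # discrete turning of an arc span pi at 41 points: pi * 39/40
        assert total == pytest.approx(np.pi * 39 / 40, rel=1e-9)

    def test_right_angle_corner(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        total, per_mm = discrete_curvature(pts)
        assert total == pytest.approx(np.pi / 2)
        assert per_mm == pytest.approx(np.pi / 2 / 2.0)

    def test_rigid_invariance_and_scaling(self, rng):
        pts = np.cumsum(rng.normal(0, 1, size=(15, 3)), axis=0)
        total, per_mm = discrete_curvature(pts)
        # random rotation + translation
        M = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(M)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = pts @ Q.T + rng.uniform(-50, 50, 3)
        total_m, per_mm_m = discrete_curvature(moved)
        assert total_m == pytest.approx(total, rel=1e-9)
        # uniform scaling: total unchanged, per-length scales by 1/s
        total_s, per_mm_s = discrete_curvature(pts * 3.0)
        assert total_s == pytest.approx(total, rel=1e-12)
        assert per_mm_s == pytest.approx(per_mm / 3.0, rel=1e-12)


class TestExtractCentroid:
    def test_single_streamline_is_itself_resampled(self):
        b = BundleSet("b", [np.array([[0, 0, 0], [10, 0, 0]], float)])
        c = extract_centroid(b, 5)
        np.testing.assert_allclose(c.points[:, 0], [0, 2.5, 5, 7.5, 10])

    def test_medoid_of_parallel_segments_is_middle(self):
        segs = [
            np.array([[0.0, y, 0.0], [10.0, y, 0.0]]) for y in (0.0, 1.0, 5.0)
        ]
        b = BundleSet("b", segs)
        c = extract_centroid(b, 5)
        assert c.points[0, 1] == pytest.approx(1.0)

    def test_agrees_with_brute_force_medoid(self, rng, random_clouds):
        streamlines = [c.points for c in random_clouds]
        b = BundleSet("b", streamlines)
        c = extract_centroid(b, 21)
        # independent exhaustive search over resampled members
        from tractoshape.geometry import resample_polyline

        members = [resample_polyline(s, 21) for s in streamlines]
        sums = [
            sum(pairwise_distance(m, o) for o in members) for m in members
        ]
        best = members[int(np.argmin(sums))]
        np.testing.assert_allclose(c.points, best.points)

    def test_empty_bundle_is_an_error(self):
        with pytest.raises(ValueError, match="must be"):
            BundleSet("b", [np.zeros((1, 3))])
        with pytest.raises(ValueError, match="no streamlines"):
            extract_centroid(BundleSet("b", []), 5)


def test_point_cloud_validation():
    with pytest.raises(ValueError):
        PointCloud(np.array([[0.0, 0.0, 0.0]]))
    with pytest.raises(ValueError):
        PointCloud(np.array([[0.0, 0.0, np.nan], [1.0, 0.0, 0.0]]))
    c = PointCloud(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))
    np.testing.assert_array_equal(c.reversed().points, c.points[::-1])
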