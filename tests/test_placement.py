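"""Local foot frame, displacement clouds, major axes and placement scoring."""
import numpy as np
import pytest

import navdrop as nd
from navdrop.placement import PointCloud


def rot(points, theta_deg):
    th = np.radians(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return np.asarray(points, float) @ R.T


def gaussian_cloud(angle_deg, n=500, sigma_major=5.0, sigma_minor=1.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.normal(0, sigma_major, n),
                           rng.normal(0, sigma_minor, n)])
    return PointCloud(rot(pts, angle_deg))


class TestLocalFrame:
    def test_hand_geometry_example(self):
        local = nd.to_local_frame(
            {"B": (5.0, 5.0), "A": (10.0, 5.0), "M": (7.0, 3.0)}, "A", "B")
        assert np.allclose(local["B"], [0.0, 0.0])
        assert np.allclose(local["A"], [5.0, 0.0])
        assert np.allclose(local["M"], [2.0, -2.0])

    def test_axis_aligned_frame_is_identity(self):
        pos = {"B": (0.0, 0.0), "A": (7.0, 0.0), "M": (3.0, 4.0)}
        local = nd.to_local_frame(pos, "A", "B")
        for mid in pos:
            assert np.allclose(local[mid], pos[mid])

    @pytest.mark.parametrize("theta", [17.0, 90.0, 133.0, 245.0])
    def test_global_rotation_invariance(self, theta):
        pos = {"B": np.array([2.0, 1.0]), "A": np.array([9.0, 4.0]),
               "M": np.array([5.0, -2.0])}
        rotated = {k: rot(v, theta) for k, v in pos.items()}
        a = nd.to_local_frame(pos, "A", "B")
        b = nd.to_local_frame(rotated, "A", "B")
        for mid in pos:
            assert np.allclose(a[mid], b[mid], atol=1e-9)

    def test_isometry_preserves_pairwise_distances(self):
        rng = np.random.default_rng(3)
        pos = {f"M{i}": rng.uniform(-50, 50, 2) for i in range(8)}
        pos["A"], pos["B"] = rng.uniform(-50, 50, 2), rng.uniform(-50, 50, 2)
        local = nd.to_local_frame(pos, "A", "B")
        ids = list(pos)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d0 = np.linalg.norm(np.asarray(pos[ids[i]]) - pos[ids[j]])
                d1 = np.linalg.norm(local[ids[i]] - local[ids[j]])
                assert d1 == pytest.approx(d0, rel=1e-9)

    def test_coincident_references_rejected(self):
        with pytest.raises(nd.DegenerateFrameError):
            nd.to_local_frame({"A": (1.0, 1.0), "B": (1.0, 1.0)}, "A", "B")


class TestDisplacementCloud:
    def test_stationary_marker_all_zero(self):
        n = 20
        series = nd.MarkerFrameSeries(
            frame=np.arange(n), t_s=np.arange(n) / 114.0,
            markers={"A": np.tile([10.0, 0.0], (n, 1)),
                     "B": np.tile([0.0, 0.0], (n, 1)),
                     "M": np.tile([5.0, 3.0], (n, 1))})
        cloud = nd.displacement_cloud(series, "M", "A", "B")
        assert np.allclose(cloud.points, 0.0)

    def test_vertical_oscillation_stays_on_y_axis(self):
        n = 50
        y = 3.0 + np.sin(np.linspace(0, 6, n))
        series = nd.MarkerFrameSeries(
            frame=np.arange(n), t_s=np.arange(n) / 114.0,
            markers={"A": np.tile([10.0, 0.0], (n, 1)),
                     "B": np.tile([0.0, 0.0], (n, 1)),
                     "M": np.column_stack([np.full(n, 5.0), y])})
        cloud = nd.displacement_cloud(series, "M", "A", "B")
        assert np.allclose(cloud.points[:, 0], 0.0, atol=1e-12)
        assert np.ptp(cloud.points[:, 1]) > 0

    def test_simulated_navicular_cloud_extent_matches_truth(self, noiseless_trial):
        trial = noiseless_trial
        cloud = nd.displacement_cloud(trial.markers, "NAV", "A", "B")
        extent_mm = np.ptp(cloud.points[:, 1]) * trial.layout.mm_per_px
        true_range = np.ptp(trial.nh_true_mm)
        assert extent_mm == pytest.approx(true_range, rel=0.05)

    def test_missing_marker_reported(self, noiseless_trial):
        with pytest.raises(nd.ParseError, match="XX"):
            nd.displacement_cloud(noiseless_trial.markers, "XX", "A", "B")


class TestMajorAxis:
    def test_vertical_pair_is_90_degrees(self):
        _, angle = nd.major_axis(PointCloud([(0.0, -1.0), (0.0, 1.0)]))
        assert angle == pytest.approx(90.0)

    def test_diagonal_line_is_45_degrees(self):
        pts = [(x, x) for x in np.linspace(-2, 2, 9)]
        _, angle = nd.major_axis(PointCloud(pts))
        assert angle == pytest.approx(45.0)

    def test_gaussian_cloud_angle_recovery(self):
        _, angle = nd.major_axis(gaussian_cloud(30.0, n=500, seed=4))
        assert angle == pytest.approx(30.0, abs=3.0)

    def test_rotation_equivariance(self):
        cloud = gaussian_cloud(10.0, n=400, seed=5)
        _, a0 = nd.major_axis(cloud)
        for theta in (25.0, 80.0, 140.0):
            _, a1 = nd.major_axis(PointCloud(rot(cloud.points, theta)))
            assert a1 == pytest.approx((a0 + theta) % 180.0, abs=1e-6)

    def test_isotropic_cloud_refused(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])  # exactly round
        with pytest.raises(nd.AxisUndefinedError):
            nd.major_axis(PointCloud(pts))


class TestAxisAngles:
    def test_identical_clouds_zero(self):
        c = gaussian_cloud(40.0, seed=6)
        assert nd.axis_angle_between(c, c) == pytest.approx(0.0)

    def test_constructed_right_angle(self):
        a = PointCloud([(-1.0, 0.0), (1.0, 0.0)])
        b = PointCloud([(0.0, -1.0), (0.0, 1.0)])
        assert nd.axis_angle_between(a, b) == pytest.approx(90.0)

    def test_attachment_cloud_pair_at_120_degrees(self):
        """Clouds constructed at 30 deg and 150 deg reproduce the ~120 deg
        separation seen between the two attachment sites' motion."""
        upper = gaussian_cloud(150.0, seed=7)
        lower = gaussian_cloud(30.0, seed=8)
        assert nd.axis_angle_between(upper, lower) == pytest.approx(120.0, abs=4.0)

    def test_symmetry(self):
        a, b = gaussian_cloud(20.0, seed=9), gaussian_cloud(75.0, seed=10)
        assert nd.axis_angle_between(a, b) == nd.axis_angle_between(b, a)


class TestAttachmentScore:
    def test_perpendicular_site_scores_zero(self):
        upper = PointCloud([(0.0, -1.0), (0.0, 1.0)])     # moves along y
        lower = gaussian_cloud(30.0, seed=11)
        assert nd.score_attachment_pair(upper, lower, (1.0, 0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_site_scores_one(self):
        upper = PointCloud([(-1.0, 0.0), (1.0, 0.0)])
        lower = gaussian_cloud(30.0, seed=12)
        assert nd.score_attachment_pair(upper, lower, (1.0, 0.0)) == pytest.approx(1.0)

    def test_perpendicular_candidate_ranked_first(self):
        sensor_line = (0.0, 1.0)  # sensor runs along y
        lower = gaussian_cloud(85.0, seed=13)
        pairs = [(gaussian_cloud(a, seed=20 + i), lower)
                 for i, a in enumerate([10.0, 40.0, 0.0, 60.0])]
        ranking = nd.rank_attachment_pairs(pairs, sensor_line)
        assert ranking[0][0] == 2  # the axis at 0 deg is perpendicular to y
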