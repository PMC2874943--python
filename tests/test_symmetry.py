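"""Centroid, PCA symmetry axis, feature snapping and axis projection."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import eyemodel as em
from eyemodel.contour import ContourPolyline
from eyemodel.errors import DegenerateInputError, InvalidArgumentError


def ellipse(a, b, theta=0.0, n=200, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    c, s = np.cos(theta), np.sin(theta)
    pts = pts @ np.array([[c, s], [-s, c]])
    return ContourPolyline(pts + center, closed=True)


def axis_error_deg(direction, expected):
    dot = abs(float(np.dot(direction, expected)))
    return np.rad2deg(np.arccos(min(dot, 1.0)))


class TestCentroid:
    def test_unit_square(self):
        c = em.centroid([ContourPolyline([[0, 0], [1, 0], [1, 1], [0, 1]])])
        assert (c.x_c, c.y_c) == (0.5, 0.5)
        assert c.n_contour == 4

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_translation_equivariance(self, a, b):
        base = ellipse(10, 4)
        shifted = ContourPolyline(base.points + [a, b], closed=True)
        c0, c1 = em.centroid([base]), em.centroid([shifted])
        assert c1.x_c == pytest.approx(c0.x_c + a, abs=1e-9)
        assert c1.y_c == pytest.approx(c0.y_c + b, abs=1e-9)

    def test_eye_slice_centroid_near_center(self):
        _, truth = em.generate_eye_slice(256, 256, 0.0, 0.0, seed=1)
        c = em.centroid(list(truth.contours.values()))
        assert abs(c.y_c - 127.5) <= 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            em.centroid([ContourPolyline([[0, 0], [1, 1]])])


class TestPcaAxis:
    def test_axis_aligned_ellipse_major_axis(self):
        axis = em.pca_symmetry_axis([ellipse(10, 4)])
        assert axis_error_deg(axis.direction, [1, 0]) < 1e-6

    @pytest.mark.parametrize("theta_deg", [15.0, 45.0, 80.0, 120.0])
    def test_rotated_ellipse_matches_eig_oracle(self, theta_deg):
        th = np.deg2rad(theta_deg)
        contour = ellipse(10, 4, theta=th)
        axis = em.pca_symmetry_axis([contour])
        # brute-force 2x2 covariance eigendecomposition oracle
        pts = contour.points - contour.points.mean(axis=0)
        evals, evecs = np.linalg.eigh(pts.T @ pts / len(pts))
        oracle = evecs[:, np.argmax(evals)]
        assert axis_error_deg(axis.direction, oracle) < 1e-9
        assert axis_error_deg(axis.direction,
                              [np.cos(th), np.sin(th)]) < 0.5

    def test_eye_slice_truth_contours(self):
        _, truth = em.generate_eye_slice(256, 256, 30.0, 0.0, seed=1)
        axis = em.pca_symmetry_axis(list(truth.contours.values()))
        expect = [np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30))]
        assert axis_error_deg(axis.direction, expect) <= 1.0
        # the adjusted axis passes through the centroid
        c = em.centroid(list(truth.contours.values()))
        assert np.allclose(axis.point, c.point)

    @pytest.mark.parametrize("theta_deg", [10.0, 70.0])
    def test_rotation_equivariance(self, theta_deg):
        th = np.deg2rad(theta_deg)
        rot = np.array([[np.cos(th), np.sin(th)],
                        [-np.sin(th), np.cos(th)]])
        base = ellipse(10, 4, theta=0.3)
        a0 = em.pca_symmetry_axis([base])
        a1 = em.pca_symmetry_axis(
            [ContourPolyline(base.points @ rot, closed=True)])
        rotated = a0.direction @ rot
        assert axis_error_deg(a1.direction, rotated) < np.rad2deg(1e-6)

    def test_noisy_symmetric_contours_within_two_degrees(self):
        _, truth = em.generate_eye_slice(256, 256, 55.0, 0.0, seed=4)
        expect = truth.axis.direction
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = [ContourPolyline(c.points
                                     + rng.normal(0, 1.0, c.points.shape),
                                     closed=True)
                     for c in truth.contours.values()]
            axis = em.pca_symmetry_axis(noisy)
            assert axis_error_deg(axis.direction, expect) <= 2.0

    def test_isotropic_point_set_rejected(self):
        with pytest.raises(DegenerateInputError):
            em.pca_symmetry_axis([ellipse(5, 5)])
        with pytest.raises(DegenerateInputError):
            em.pca_symmetry_axis([ContourPolyline([[1, 1]] * 5)])


class TestSnapFeaturePoints:
    def test_click_on_vertex_returns_vertex(self):
        contour = ellipse(10, 4)
        fp = em.snap_feature_points(contour.points[:3], contour, d_max=5)
        assert np.allclose(fp.points, contour.points[:3])

    def test_threshold_semantics(self):
        contour = ContourPolyline([[0, 0], [10, 0], [10, 10], [0, 10]])
        click = np.array([[0.0, 3.0]])  # distance 3 from (0, 0)
        near = em.snap_feature_points(click, contour, d_max=5)
        far = em.snap_feature_points(click, contour, d_max=2)
        assert np.allclose(near.points[0], [0, 0])
        assert np.allclose(far.points[0], [0, 3])

    def test_matches_bruteforce_nearest_vertex(self):
        rng = np.random.default_rng(0)
        contour = ellipse(12, 7, theta=0.4, n=97)
        clicks = rng.uniform(-15, 15, size=(50, 2))
        fp = em.snap_feature_points(clicks, contour, d_max=4.0)
        for click, snapped in zip(clicks, fp.points):
            d = np.linalg.norm(contour.points - click, axis=1)
            if d.min() <= 4.0:
                assert np.allclose(snapped, contour.points[np.argmin(d)])
            else:
                assert np.allclose(snapped, click)


class TestProjectOntoAxis:
    def test_idempotence_and_simple_case(self, x_axis):
        foot = em.project_onto_axis([0.3, 0.4], x_axis)
        assert np.allclose(foot, [0.3, 0.0])
        assert np.allclose(em.project_onto_axis(foot, x_axis), foot,
                           atol=1e-12)

    def test_matches_slope_intercept_oracle(self):
        """Vector projection equals the explicit perpendicular-foot
        construction through the axis slope and intercept."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            xk, yk = rng.uniform(-50, 50, 2)
            xc, yc = rng.uniform(-50, 50, 2)
            if abs(xc - xk) < 1e-3 or abs(yc - yk) < 1e-3:
                continue
            x0, y0 = rng.uniform(-50, 50, 2)
            k = (yc - yk) / (xc - xk)
            kp = -1.0 / k
            b = yk - xk / (xc - xk) * (yc - yk)
            bp = y0 - kp * x0
            x0p = -(b - bp) / (k - kp)
            y0p = k * x0p + b
            axis = em.SymmetryAxis(point=np.array([xk, yk]),
                                   direction=np.array([xc - xk, yc - yk]))
            foot = em.project_onto_axis([x0, y0], axis)
            assert np.allclose(foot, [x0p, y0p], atol=1e-9)

    def test_foot_on_axis_and_distance_minimizing(self):
        axis = em.SymmetryAxis(point=np.array([1.0, 2.0]),
                               direction=np.array([3.0, 4.0]))
        p = np.array([-2.0, 5.0])
        foot = em.project_onto_axis(p, axis)
        rel = foot - axis.point
        d = axis.direction
        assert abs(d[0] * rel[1] - d[1] * rel[0]) <= 1e-9
        ts = np.arange(-20, 20, 1e-3)
        candidates = axis.point + np.outer(ts, axis.direction)
        dmin = np.linalg.norm(candidates - p, axis=1).min()
        assert np.linalg.norm(foot - p) <= dmin + 1e-9

    def test_pole_candidates_projected_within_band(self, x_axis):
        fp = em.FeaturePointSet(np.array([[5.0, 2.0], [8.0, 30.0]]))
        out = em.project_pole_candidates(fp, x_axis, band=15.0)
        assert np.allclose(out.points[0], [5.0, 0.0])
        assert out.on_axis_flags[0] and not out.on_axis_flags[1]
        assert np.allclose(out.points[1], [8.0, 30.0])
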