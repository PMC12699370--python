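import numpy as np
import pytest

from cytocurv import geometry
from cytocurv.exceptions import DegenerateContourError, ParameterError
from cytocurv.geometry import (
    resample_contour,
    shoelace_area,
    signed_curvature,
    smooth_abs_curvature,
)


class TestResampleContour:
    def test_square_perimeter_preserved(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        c = resample_contour(square, pixel_size_um=1.0, n_samples=400)
        assert c.perimeter == pytest.approx(4.0, rel=0.005)

    def test_circle_invariance(self, circle_points):
        c = resample_contour(circle_points(radius=10.0, n=64), 1.0, n_samples=256)
        radii = np.linalg.norm(c.points, axis=1)
        assert np.all(np.abs(radii - 10.0) < 0.05)

    def test_clockwise_input_flipped_ccw(self, circle_points):
        c = resample_contour(circle_points(clockwise=True), 1.0, n_samples=128)
        assert shoelace_area(c.points) > 0
        assert c.is_counterclockwise

    def test_uniform_spacing(self, ellipse_points):
        c = resample_contour(ellipse_points(), 1.0, n_samples=500)
        spacings = np.diff(c.arc_positions)
        assert np.allclose(spacings, spacings[0], rtol=1e-6)

    def test_pixel_size_scaling(self, circle_points):
        c = resample_contour(circle_points(radius=50.0), 0.2, n_samples=256)
        assert c.perimeter == pytest.approx(2 * np.pi * 10.0, rel=1e-3)
        assert c.pixel_size_um == 0.2

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateContourError):
            resample_contour(np.array([[0, 0], [1, 1]], dtype=float), 1.0)

    def test_duplicate_points_dropped(self):
        pts = np.array([[0, 0], [0, 0], [1, 0]], dtype=float)
        with pytest.raises(DegenerateContourError):
            resample_contour(pts, 1.0)

    def test_self_intersection_warns_but_proceeds(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.warns(UserWarning, match="self-intersect"):
            c = resample_contour(bowtie, 1.0, n_samples=64)
        assert c.n_samples == 64

    def test_bad_parameters(self, circle_points):
        with pytest.raises(ParameterError):
            resample_contour(circle_points(), 0.0)
        with pytest.raises(ParameterError):
            resample_contour(circle_points(), 1.0, n_samples=4)


class TestSignedCurvature:
    def test_circle_radius_5(self, circle_points):
        c = resample_contour(circle_points(radius=5.0), 1.0, n_samples=1000)
        prof = signed_curvature(c)
        assert np.all(np.abs(prof.kappa - 0.2) < 0.002)

    def test_circle_radius_2(self, circle_points):
        c = resample_contour(circle_points(radius=2.0), 1.0, n_samples=1000)
        prof = signed_curvature(c)
        assert np.all(np.abs(np.abs(prof.kappa) - 0.5) < 0.005)

    def test_ellipse_tip_curvature(self, ellipse_points):
        # closed form: kappa at the end of the major axis = a / b^2
        a, b = 10.0, 5.0
        c = resample_contour(ellipse_points(a, b), 1.0, n_samples=2000)
        prof = signed_curvature(c)
        tip = np.argmax(c.points[:, 0])
        assert prof.kappa[tip] == pytest.approx(a / b**2, rel=0.02)

    def test_ellipse_vs_dense_numerical_oracle(self, ellipse_points):
        # independent oracle: dense central differences on the analytic curve
        a, b = 10.0, 5.0
        t = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
        x, y = a * np.cos(t), b * np.sin(t)
        dt = t[1] - t[0]
        x1 = np.gradient(x, dt, edge_order=2)
        y1 = np.gradient(y, dt, edge_order=2)
        x2 = np.gradient(x1, dt, edge_order=2)
        y2 = np.gradient(y1, dt, edge_order=2)
        oracle_tip = ((x1 * y2 - y1 * x2) / (x1**2 + y1**2) ** 1.5)[0]
        assert oracle_tip == pytest.approx(a / b**2, rel=1e-4)

        c = resample_contour(ellipse_points(a, b), 1.0, n_samples=2000)
        prof = signed_curvature(c)
        tip = np.argmax(c.points[:, 0])
        assert prof.kappa[tip] == pytest.approx(oracle_tip, rel=0.02)

    def test_window_exceeding_half_perimeter_raises(self, circle_points):
        c = resample_contour(circle_points(radius=2.0), 1.0, n_samples=256)
        with pytest.raises(ParameterError):
            signed_curvature(c, presmooth_window_um=c.perimeter)

    def test_total_turning_is_2pi(self, circle_points, ellipse_points):
        for pts in (circle_points(radius=7.0), ellipse_points(8.0, 3.0)):
            c = resample_contour(pts, 1.0, n_samples=1000)
            prof = signed_curvature(c)
            assert prof.total_turning == pytest.approx(2 * np.pi, rel=0.01)

    @pytest.mark.parametrize("factor", [0.5, 2.0, 10.0])
    def test_scale_covariance(self, ellipse_points, factor):
        pts = ellipse_points()
        base = signed_curvature(
            resample_contour(pts, 1.0, 1000), presmooth_window_um=1.0
        )
        scaled = signed_curvature(
            resample_contour(pts * factor, 1.0, 1000),
            presmooth_window_um=1.0 * factor,
        )
        assert np.allclose(scaled.kappa, base.kappa / factor, rtol=1e-6)

    def test_rigid_motion_invariance(self, ellipse_points):
        pts = ellipse_points()
        angle = 0.7
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + np.array([13.0, -4.5])
        base = signed_curvature(resample_contour(pts, 1.0, 1000))
        transformed = signed_curvature(resample_contour(moved, 1.0, 1000))
        assert np.allclose(transformed.kappa, base.kappa, atol=1e-9)

    def test_three_point_osculating_circle_equivalence(self, ellipse_points):
        # independent estimator: signed circumcircle curvature of point
        # triplets (i - m, i, i + m) on the noise-free analytic shape
        c = resample_contour(ellipse_points(), 1.0, n_samples=2000)
        prof = signed_curvature(c)
        m = 8
        p0 = np.roll(c.points, m, axis=0)
        p1 = c.points
        p2 = np.roll(c.points, -m, axis=0)
        a = p1 - p0
        b = p2 - p1
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(p2 - p0, axis=1)
        osculating = 2 * cross / (la * lb * lc)
        assert np.allclose(prof.kappa, osculating, rtol=0.02)


class TestSmoothAbsCurvature:
    def _flat_profile(self, n=500, value=0.3, ds=0.1):
        s = ds * np.arange(n)
        kappa = np.full(n, value)
        return geometry.CurvatureProfile(s=s, kappa=kappa, kappa_abs_smoothed=kappa)

    def test_constant_profile_unchanged(self):
        prof = self._flat_profile()
        out = smooth_abs_curvature(prof, window_um=2.0)
        assert np.allclose(out.kappa_abs_smoothed, 0.3, atol=1e-9)

    def test_single_spike_moving_average(self):
        n, ds = 200, 0.1
        kappa = np.zeros(n)
        kappa[50] = 10.0
        prof = geometry.CurvatureProfile(
            s=ds * np.arange(n), kappa=kappa, kappa_abs_smoothed=np.abs(kappa)
        )
        window_um = 0.5  # k = 5 samples
        out = smooth_abs_curvature(prof, window_um=window_um)
        assert out.kappa_abs_smoothed.max() == pytest.approx(10.0 / 5)

    def test_sinusoid_period_equal_to_window(self):
        # oracle: brute-force periodic convolution with a boxcar
        n, ds = 400, 0.05
        k_window = 40
        s = ds * np.arange(n)
        kappa = 0.5 + 0.2 * np.sin(2 * np.pi * s / (k_window * ds))
        prof = geometry.CurvatureProfile(
            s=s, kappa=kappa, kappa_abs_smoothed=np.abs(kappa)
        )
        out = smooth_abs_curvature(prof, window_um=k_window * ds)

        kernel = np.zeros(n)
        idx = (np.arange(k_window) - k_window // 2) % n
        kernel[idx] = 1.0 / k_window
        oracle = np.real(np.fft.ifft(np.fft.fft(np.abs(kappa)) * np.fft.fft(kernel)))
        assert np.allclose(out.kappa_abs_smoothed, oracle, atol=1e-9)
        assert np.all(np.abs(out.kappa_abs_smoothed - 0.5) < 0.01 * 0.2)

    def test_non_positive_window_raises(self):
        with pytest.raises(ParameterError):
            smooth_abs_curvature(self._flat_profile(), window_um=0.0)

    def test_result_non_negative(self):
        rng = np.random.default_rng(0)
        kappa = rng.normal(0, 1, 300)
        prof = geometry.CurvatureProfile(
            s=0.1 * np.arange(300), kappa=kappa, kappa_abs_smoothed=np.abs(kappa)
        )
        out = smooth_abs_curvature(prof, window_um=0.7)
        assert np.all(out.kappa_abs_smoothed >= 0)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, ellipse_points):
        c = resample_contour(ellipse_points(), 0.5, n_samples=300)
        prof = smooth_abs_curvature(signed_curvature(c), window_um=2.0)
        frame = geometry.contour_profile_frame(c, prof)
        path = tmp_path / "profile.csv"
        frame.to_csv(path, index=False)
        c2, p2 = geometry.read_contour_profile_csv(path, pixel_size_um=0.5)
        assert np.allclose(c2.points, c.points)
        assert np.allclose(p2.kappa, prof.kappa)
        assert np.allclose(p2.kappa_abs_smoothed, prof.kappa_abs_smoothed)

    def test_frame_columns(self, circle_points):
        c = resample_contour(circle_points(), 1.0, n_samples=100)
        prof = signed_curvature(c)
        frame = geometry.contour_profile_frame(c, prof)
        assert list(frame.columns) == [
            "index",
            "s_um",
            "x_um",
            "y_um",
            "kappa_per_um",
            "kappa_abs_smoothed_per_um",
        ]
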