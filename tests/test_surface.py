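"""Surface fitting and curvature descriptors against analytic surfaces."""

import math

import numpy as np
import pytest

import memcurve as mc
from memcurve.errors import ValidationError
from memcurve.surface import surface_area
from memcurve.synthetic import uniform_tilt_grid

from .conftest import sinusoid_model


class TestFitSurface:
    def test_constant_field_exact(self, plane_cloud):
        frame, _ = plane_cloud
        grid = mc.fit_surface(frame, "upper", 16, 16, bandwidth=1.0)
        assert np.allclose(grid.heights, 3.0)
        assert np.allclose(grid.theta, 0.0)

    def test_sinusoid_rms_within_two_percent(self, dense_sinusoid):
        frame, _ = mc.gen_surface_cloud(dense_sinusoid)
        grid = mc.fit_surface(frame, "upper", 64, 64)
        gx = np.arange(64) * 10.0 / 64
        analytic = 2.0 + 1.0 * np.sin(2 * np.pi * gx / 10.0)
        rms = np.sqrt(np.mean((grid.heights - analytic[:, None]) ** 2))
        assert rms < 0.02  # 2% of the 1 nm amplitude

    def test_periodic_translation_equivariance(self):
        """Translating the cloud by one grid cell cyclically shifts the
        fitted heights."""
        model = sinusoid_model(amplitude=0.8, n=500, seed=5)
        frame, _ = mc.gen_surface_cloud(model)
        nx = 20
        step = 10.0 / nx  # one grid cell in x
        shifted = mc.LipidFrame(
            positions=frame.positions + np.array([step, 0.0, 0.0]),
            leaflet=frame.leaflet,
            box=frame.box,
        )
        a = mc.fit_surface(frame, "upper", nx, nx, bandwidth=0.8)
        b = mc.fit_surface(shifted, "upper", nx, nx, bandwidth=0.8)
        assert np.allclose(b.heights, np.roll(a.heights, 1, axis=0), atol=1e-9)

    def test_empty_leaflet_rejected(self):
        frame = mc.LipidFrame(
            positions=np.random.default_rng(0).uniform(0, 5, (20, 3)),
            leaflet=np.array(["upper"] * 20),
            box=(5.0, 5.0),
        )
        with pytest.raises(ValidationError):
            mc.fit_surface(frame, "lower", 8, 8, bandwidth=1.0)

    def test_small_bandwidth_warns_in_output(self, plane_cloud):
        frame, _ = plane_cloud
        grid = mc.fit_surface(frame, "upper", 8, 8, bandwidth=1e-3)
        assert grid.warnings and "bandwidth" in grid.warnings[0]


class TestOrderParameter:
    def test_planar_grid_is_exactly_one(self, plane_cloud):
        frame, _ = plane_cloud
        grid = mc.fit_surface(frame, "upper", 16, 16, bandwidth=1.0)
        assert mc.curvature_order_parameter(grid) == pytest.approx(1.0)

    def test_uniform_quarter_turn_normals(self):
        grid = uniform_tilt_grid(math.pi / 2)
        assert mc.curvature_order_parameter(grid) == pytest.approx(-0.5)

    def test_sinusoid_matches_quadrature_oracle(self, dense_sinusoid):
        frame, oracle = mc.gen_surface_cloud(dense_sinusoid)
        grid = mc.fit_surface(frame, "upper", 64, 64)
        s_c = mc.curvature_order_parameter(grid)
        assert s_c == pytest.approx(oracle, rel=0.01)

    def test_amplitude_monotonicity(self):
        """Fixed wavelength: larger undulation amplitude means lower S_C
        (more curvature), for both the oracle and the fitted estimate."""
        oracles, fitted = [], []
        for amp in (0.25, 0.5, 1.0, 2.0):
            frame, oracle = mc.gen_surface_cloud(
                sinusoid_model(amplitude=amp, n=2000, seed=3)
            )
            grid = mc.fit_surface(frame, "upper", 48, 48)
            oracles.append(oracle)
            fitted.append(mc.curvature_order_parameter(grid))
        assert np.all(np.diff(oracles) < 0)
        assert np.all(np.diff(fitted) < 0)

    def test_upper_bound_one(self):
        for amp in (0.0, 0.7, 1.5):
            frame, _ = mc.gen_surface_cloud(
                sinusoid_model(amplitude=amp, n=600, seed=9, jitter=0.05)
            )
            grid = mc.fit_surface(frame, "upper", 24, 24)
            assert mc.curvature_order_parameter(grid) <= 1.0

    def test_bud_lower_than_equal_rms_sinusoid(self):
        """The suite's budded fixture concentrates steep normals and
        scores below the sinusoid of equal mean-removed RMS height."""
        bud_model = mc.SurfaceModel(
            "spherical_bud",
            {"height": 0.0, "radius": 4.0, "cap_angle": 1.0},
            box=(10.0, 10.0), n_lipids_per_leaflet=16,
        )
        _, bud_oracle = mc.gen_surface_cloud(bud_model)
        x = np.linspace(0, 10, 401)
        X, Y = np.meshgrid(x, x)
        h = bud_model.height(X, Y)
        amp = math.sqrt(2.0 * float(np.mean((h - h.mean()) ** 2)))
        sin_model = sinusoid_model(amplitude=amp, n=16)
        _, sin_oracle = mc.gen_surface_cloud(sin_model)
        assert bud_oracle < sin_oracle


class TestAreaAndThickness:
    def test_projected_area_per_lipid(self, plane_cloud):
        frame, _ = plane_cloud
        grid = mc.fit_surface(frame, "upper", 16, 16, bandwidth=1.0)
        # 8x8 nm box, 128 lipids -> 0.5 nm^2 = 50 A^2
        assert mc.area_per_lipid(grid, 128, "projected") == pytest.approx(50.0)

    def test_flat_surface_mode_equals_projected(self, plane_cloud):
        frame, _ = plane_cloud
        grid = mc.fit_surface(frame, "upper", 16, 16, bandwidth=1.0)
        assert mc.area_per_lipid(grid, 128, "surface") == pytest.approx(
            mc.area_per_lipid(grid, 128, "projected"), abs=1e-9
        )

    def test_sinusoid_surface_excess_matches_arc_length(self, dense_sinusoid):
        frame, _ = mc.gen_surface_cloud(dense_sinusoid)
        grid = mc.fit_surface(frame, "upper", 64, 64)
        x = np.linspace(0.0, 10.0, 100001)
        hp = (2 * np.pi / 10.0) * np.cos(2 * np.pi * x / 10.0)
        arc_factor = np.trapezoid(np.sqrt(1 + hp**2), x) / 10.0
        ratio = surface_area(grid) / (10.0 * 10.0)
        assert ratio == pytest.approx(arc_factor, rel=0.01)

    def test_surface_never_below_projected(self):
        for amp in (0.0, 0.5, 1.5):
            frame, _ = mc.gen_surface_cloud(
                sinusoid_model(amplitude=amp, n=800, seed=2, jitter=0.1)
            )
            grid = mc.fit_surface(frame, "upper", 32, 32)
            n = frame.count("upper")
            assert (
                mc.area_per_lipid(grid, n, "surface")
                >= mc.area_per_lipid(grid, n, "projected") - 1e-9
            )

    def test_parallel_planes_thickness(self):
        rng = np.random.default_rng(1)
        n = 100
        pos = np.vstack([
            np.column_stack([rng.uniform(0, 6, n), rng.uniform(0, 6, n),
                             np.full(n, 2.0)]),
            np.column_stack([rng.uniform(0, 6, n), rng.uniform(0, 6, n),
                             np.full(n, -2.0)]),
        ])
        frame = mc.LipidFrame(
            positions=pos,
            leaflet=np.array(["upper"] * n + ["lower"] * n),
            box=(6.0, 6.0),
        )
        upper = mc.fit_surface(frame, "upper", 16, 16, bandwidth=1.0)
        lower = mc.fit_surface(frame, "lower", 16, 16, bandwidth=1.0)
        res = mc.membrane_thickness(upper, lower)
        assert res["d_hh_nm"] == pytest.approx(4.0)
        assert res["negative_nodes"] == 0
        # translation invariance
        shifted = mc.LipidFrame(
            positions=pos + np.array([0.0, 0.0, 1.0]),
            leaflet=frame.leaflet, box=frame.box,
        )
        up2 = mc.fit_surface(shifted, "upper", 16, 16, bandwidth=1.0)
        lo2 = mc.fit_surface(shifted, "lower", 16, 16, bandwidth=1.0)
        assert mc.membrane_thickness(up2, lo2)["d_hh_nm"] == pytest.approx(4.0)

    def test_in_phase_sinusoids_constant_separation(self):
        model = sinusoid_model(amplitude=0.8, n=2000, seed=4)
        frame, _ = mc.gen_surface_cloud(model)  # lower = upper − 4 nm
        upper = mc.fit_surface(frame, "upper", 32, 32)
        lower = mc.fit_surface(frame, "lower", 32, 32)
        res = mc.membrane_thickness(upper, lower)
        assert res["d_hh_nm"] == pytest.approx(4.0, abs=0.05)

    def test_resolution_mismatch_rejected(self, plane_cloud):
        frame, _ = plane_cloud
        a = mc.fit_surface(frame, "upper", 16, 16, bandwidth=1.0)
        b = mc.fit_surface(frame, "lower", 8, 8, bandwidth=1.0)
        with pytest.raises(ValidationError):
            mc.membrane_thickness(a, b)


class TestTrajectorySummary:
    def _frames(self, amplitudes, n=400):
        frames = []
        for i, amp in enumerate(amplitudes):
            frame, _ = mc.gen_surface_cloud(
                sinusoid_model(amplitude=amp, n=n, seed=100 + i)
            )
            frames.append(frame)
        return frames

    def test_repeated_frame_degenerate_stats(self):
        frames = self._frames([0.5]) * 3
        summary = mc.trajectory_summary(frames, nx=24, ny=24)
        assert summary.s_c_iqr == 0.0
        assert summary.s_c_mean == pytest.approx(
            summary.per_frame["S_C"][0]
        )

    def test_two_frame_statistics(self):
        frames = self._frames([0.0, 1.0])
        summary = mc.trajectory_summary(frames, nx=24, ny=24)
        vals = summary.per_frame["S_C"]
        assert summary.s_c_mean == pytest.approx(np.mean(vals))
        assert summary.s_c_median == pytest.approx(np.median(vals))

    def test_decaying_amplitude_series_increases_toward_one(self):
        frames = self._frames([1.6, 1.2, 0.8, 0.4, 0.0], n=800)
        summary = mc.trajectory_summary(frames, nx=32, ny=32)
        s = summary.per_frame["S_C"]
        assert np.all(np.diff(s) > 0)
        assert s[-1] == pytest.approx(1.0, abs=1e-6)

    def test_empty_window_rejected(self):
        frames = self._frames([0.5])
        with pytest.raises(ValidationError):
            mc.trajectory_summary(frames, nx=16, ny=16, window=slice(5, 5))


class TestRigidMotionInvariance:
    def test_translation_and_quarter_rotation(self):
        model = sinusoid_model(amplitude=0.6, n=1200, seed=6)
        frame, _ = mc.gen_surface_cloud(model)
        base = mc.analyze_frame(frame, nx=32, ny=32, bandwidth=0.6)
        # in-plane translation (with wrap)
        t_frame = mc.LipidFrame(
            positions=frame.positions + np.array([2.3, 1.1, 0.0]),
            leaflet=frame.leaflet, box=frame.box,
        )
        trans = mc.analyze_frame(t_frame, nx=32, ny=32, bandwidth=0.6)
        # 90-degree rotation in the square box: (x, y) -> (y, Lx - x)
        rot_pos = frame.positions.copy()
        rot_pos[:, 0], rot_pos[:, 1] = (
            frame.positions[:, 1],
            frame.box[0] - frame.positions[:, 0],
        )
        r_frame = mc.LipidFrame(positions=rot_pos, leaflet=frame.leaflet,
                                box=frame.box)
        rot = mc.analyze_frame(r_frame, nx=32, ny=32, bandwidth=0.6)
        for res in (trans, rot):
            assert res["S_C"] == pytest.approx(base["S_C"], abs=1e-6)
            assert res["A_L_A2"] == pytest.approx(base["A_L_A2"], abs=1e-6)
            assert res["D_HH_nm"] == pytest.approx(base["D_HH_nm"], abs=1e-6)
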