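"""Lateral pressure profile, midplane centring, moment integrals,
unit conversions and the leaflet-asymmetry ordering."""

import math

import numpy as np
import pytest

import memcurve as mc
from memcurve import units
from memcurve.datatypes import shift_profile
from memcurve.errors import CenteringError, RangeError, ValidationError
from memcurve.synthetic import bilayer_bumps


def make_profile(z, lpp):
    return mc.LateralPressureProfile(z=np.asarray(z, float),
                                     lpp=np.asarray(lpp, float))


class TestComputeLpp:
    def test_isotropic_stress_vanishes(self):
        z = np.linspace(-2, 2, 64)
        p = np.sin(z) * 50.0
        stress = mc.StressProfile(z=z, pxx=p, pyy=p, pzz=p)
        assert np.allclose(mc.compute_lpp(stress).lpp, 0.0)

    def test_pointwise_arithmetic(self):
        z = np.linspace(-1, 1, 8)
        pxx = np.full(8, -100.0)
        stress = mc.StressProfile(z=z, pxx=pxx, pyy=pxx, pzz=np.zeros(8))
        assert np.allclose(mc.compute_lpp(stress).lpp, -100.0)

    def test_generator_round_trip(self, single_bump_model):
        stress, _ = mc.gen_stress_profile(single_bump_model)
        profile = mc.compute_lpp(stress)
        assert np.allclose(profile.lpp, single_bump_model.lpp(profile.z),
                           atol=1e-9)

    def test_nonuniform_grid_rejected(self):
        z = np.array([0.0, 0.1, 0.25, 0.5])
        with pytest.raises(ValidationError, match="uniform"):
            mc.StressProfile(z=z, pxx=z, pyy=z, pzz=z)


class TestCenterMidplane:
    @pytest.fixture
    def symmetric_profile(self):
        model = mc.StressFieldModel(bumps=bilayer_bumps(), z_range=(-4.5, 4.5),
                                    n_points=601)
        stress, _ = mc.gen_stress_profile(model)
        return mc.compute_lpp(stress)

    def test_already_centred_fixed_point(self, symmetric_profile):
        centred = mc.center_midplane(symmetric_profile)
        assert centred.midplane_shift == pytest.approx(0.0, abs=1e-9)

    def test_translation_inverse(self, symmetric_profile):
        translated = shift_profile(symmetric_profile, 0.7)
        recentred = mc.center_midplane(
            mc.LateralPressureProfile(z=translated.z, lpp=translated.lpp)
        )
        dz = symmetric_profile.spacing
        assert recentred.midplane_shift == pytest.approx(-0.7, abs=dz)
        assert np.allclose(recentred.z, symmetric_profile.z, atol=dz)

    def test_idempotent(self, symmetric_profile):
        once = mc.center_midplane(shift_profile(symmetric_profile, 0.3))
        twice = mc.center_midplane(once)
        assert twice.midplane_shift == pytest.approx(once.midplane_shift,
                                                     abs=1e-9)

    def test_all_zero_profile_fails_with_diagnostic(self):
        profile = make_profile(np.linspace(-2, 2, 32), np.zeros(32))
        with pytest.raises(CenteringError):
            mc.center_midplane(profile)


class TestMoments:
    def test_even_profile_zero_bending_moment(self, wide_bounds):
        z = np.linspace(-3, 3, 513)
        profile = make_profile(z, 80.0 * np.exp(-(z**2) / 0.5))
        ec = mc.bending_moment(profile, wide_bounds)
        assert ec.bending_moment_bar_nm2 == pytest.approx(0.0, abs=1e-9)

    def test_single_bump_first_moment(self, single_bump_model, wide_bounds):
        stress, truth = mc.gen_stress_profile(single_bump_model)
        profile = mc.compute_lpp(stress)
        ec = mc.bending_moment(profile, wide_bounds)
        assert ec.bending_moment_bar_nm2 == pytest.approx(50.13, abs=0.01)
        assert ec.bending_moment_pn == pytest.approx(5.013, abs=0.001)
        assert ec.bending_moment_bar_nm2 == pytest.approx(
            truth.bending_moment_bar_nm2, rel=1e-3
        )

    def test_single_bump_gaussian_modulus(self, single_bump_model, wide_bounds):
        stress, truth = mc.gen_stress_profile(single_bump_model)
        profile = mc.compute_lpp(stress)
        ec = mc.gaussian_modulus(profile, wide_bounds, temperature=303.15)
        assert ec.gaussian_modulus_bar_nm3 == pytest.approx(-52.14, abs=0.01)
        assert ec.gaussian_modulus_kbt == pytest.approx(-1.25, abs=0.01)
        assert ec.gaussian_modulus_bar_nm3 == pytest.approx(
            truth.gaussian_modulus_bar_nm3, rel=1e-3
        )

    def test_zero_profile_zero_moments(self, wide_bounds):
        profile = make_profile(np.linspace(-3, 3, 64), np.zeros(64))
        ec = mc.elastic_constants(profile, wide_bounds)
        assert ec.bending_moment_bar_nm2 == 0.0
        assert ec.gaussian_modulus_bar_nm3 == 0.0

    def test_reflection_parity(self, wide_bounds):
        z = np.linspace(-3, 3, 513)
        lpp = 100.0 * np.exp(-((z - 1.0) ** 2) / 0.08) - 40.0 * np.exp(
            -((z + 0.5) ** 2) / 0.18
        )
        fwd = mc.elastic_constants(make_profile(z, lpp), wide_bounds)
        rev = mc.elastic_constants(make_profile(z, lpp[::-1]), wide_bounds)
        assert rev.bending_moment_bar_nm2 == pytest.approx(
            -fwd.bending_moment_bar_nm2, rel=1e-12
        )
        assert rev.gaussian_modulus_bar_nm3 == pytest.approx(
            fwd.gaussian_modulus_bar_nm3, rel=1e-12
        )

    def test_moment_linearity(self, wide_bounds):
        z = np.linspace(-3, 3, 257)
        a = 50.0 * np.exp(-((z - 0.8) ** 2) / 0.1)
        b = -30.0 * np.exp(-((z + 1.2) ** 2) / 0.2)
        ec_a = mc.elastic_constants(make_profile(z, a), wide_bounds)
        ec_b = mc.elastic_constants(make_profile(z, b), wide_bounds)
        ec_ab = mc.elastic_constants(make_profile(z, a + b), wide_bounds)
        assert ec_ab.bending_moment_bar_nm2 == pytest.approx(
            ec_a.bending_moment_bar_nm2 + ec_b.bending_moment_bar_nm2,
            rel=1e-12,
        )
        assert ec_ab.gaussian_modulus_bar_nm3 == pytest.approx(
            ec_a.gaussian_modulus_bar_nm3 + ec_b.gaussian_modulus_bar_nm3,
            rel=1e-12,
        )

    def test_grid_refinement_convergence(self):
        """Halving the grid spacing shrinks the moment error by at least
        the O(h²) factor on a smooth profile (trapezoid does better still
        on rapidly decaying integrands)."""
        def moment_error(n):
            model = mc.StressFieldModel(
                bumps=((100.0, 1.0, 0.25),), z_range=(-3.0, 3.0), n_points=n
            )
            stress, truth = mc.gen_stress_profile(model)
            profile = mc.compute_lpp(stress)
            ec = mc.elastic_constants(profile, mc.MembraneBounds(-3.0, 3.0))
            return abs(ec.bending_moment_bar_nm2 - truth.bending_moment_bar_nm2)

        e_coarse, e_fine = moment_error(17), moment_error(33)
        assert e_fine < e_coarse / 4.0

    def test_bounds_outside_grid_rejected(self, single_bump_model):
        stress, _ = mc.gen_stress_profile(single_bump_model)
        profile = mc.compute_lpp(stress)
        with pytest.raises(RangeError):
            mc.bending_moment(profile, mc.MembraneBounds(-10.0, 10.0))


class TestDetectBounds:
    def test_encloses_bump_pair_support(self):
        model = mc.StressFieldModel(
            bumps=((100.0, 1.4, 0.2), (-100.0, -1.4, 0.2)),
            z_range=(-4.0, 4.0), n_points=801,
        )
        stress, _ = mc.gen_stress_profile(model)
        profile = mc.compute_lpp(stress)
        bounds = mc.detect_bounds(profile)
        dz = profile.spacing
        # analytic support at f=0.01 of max: |z ∓ 1.4| = sigma*sqrt(2 ln 100)
        edge = 1.4 + 0.2 * math.sqrt(2 * math.log(100.0))
        assert bounds.d_plus == pytest.approx(edge + dz, abs=2 * dz)
        assert bounds.d_minus == pytest.approx(-edge - dz, abs=2 * dz)

    def test_explicit_override_verbatim(self, single_bump_model):
        stress, _ = mc.gen_stress_profile(single_bump_model)
        profile = mc.compute_lpp(stress)
        bounds = mc.detect_bounds(profile, explicit=(-1.25, 2.5))
        assert (bounds.d_minus, bounds.d_plus) == (-1.25, 2.5)
        assert bounds.detection_rule == "explicit"

    def test_tail_insensitivity(self):
        """With a tight support threshold, widening to the full box moves
        the moments by less than 0.1%."""
        model = mc.StressFieldModel(
            bumps=bilayer_bumps(outer_gain=2.0), z_range=(-4.5, 4.5),
            n_points=901,
        )
        stress, _ = mc.gen_stress_profile(model)
        profile = mc.compute_lpp(stress)
        tight = mc.elastic_constants(
            profile, mc.detect_bounds(profile, support_fraction=1e-4)
        )
        full = mc.elastic_constants(
            profile, mc.detect_bounds(profile, full_box=True)
        )
        assert tight.bending_moment_bar_nm2 == pytest.approx(
            full.bending_moment_bar_nm2, rel=1e-3
        )
        assert tight.gaussian_modulus_bar_nm3 == pytest.approx(
            full.gaussian_modulus_bar_nm3, rel=1e-3
        )

    def test_degenerate_profile_rejected(self):
        profile = make_profile(np.linspace(-2, 2, 32), np.zeros(32))
        with pytest.raises(mc.errors.DegenerateProfileError):
            mc.detect_bounds(profile)


class TestCurvatureRadius:
    @pytest.mark.parametrize(
        "c0,expected",
        [(-0.015, 66.67), (1.0, 1.0), (-0.5, 2.0)],
    )
    def test_radius(self, c0, expected):
        assert mc.curvature_radius(c0) == pytest.approx(expected, abs=0.005)

    def test_flat_membrane_distinguished_value(self):
        assert mc.curvature_radius(0.0) == math.inf


class TestUnits:
    def test_bar_nm2_pn_round_trip(self):
        m = 37.5
        assert (m * units.BAR_NM2_TO_PN) / units.BAR_NM2_TO_PN == m

    def test_kbt_bar_nm3_round_trip(self):
        v = -52.14
        assert units.kbt_to_bar_nm3(
            units.bar_nm3_to_kbt(v, 303.15), 303.15
        ) == pytest.approx(v, rel=1e-15)

    def test_elastic_constants_unit_consistency(self):
        ec = mc.ElasticConstants(50.0, -52.0, temperature=303.15)
        assert ec.bending_moment_pn == pytest.approx(5.0)
        expected_kbt = -52.0 * 1e-22 / (1.380649e-23 * 303.15)
        assert ec.gaussian_modulus_kbt == pytest.approx(expected_kbt, rel=1e-12)


class TestLeafletAsymmetryOrdering:
    def test_amplified_outer_leaflet_orders_moments(self):
        """An asymmetric membrane (amplified outer-leaflet stress) must
        show a strictly larger bending moment and a more negative
        Gaussian modulus than the symmetric control."""
        results = {}
        for name, gain in (("sym", 1.0), ("asym", 2.5)):
            model = mc.StressFieldModel(
                bumps=bilayer_bumps(outer_gain=gain), z_range=(-4.5, 4.5)
            )
            stress, _ = mc.gen_stress_profile(model)
            profile = mc.center_midplane(mc.compute_lpp(stress))
            results[name] = mc.elastic_constants(
                profile, mc.detect_bounds(profile, full_box=True)
            )
        assert (
            results["asym"].bending_moment_bar_nm2
            > results["sym"].bending_moment_bar_nm2
        )
        assert (
            results["asym"].gaussian_modulus_bar_nm3
            < results["sym"].gaussian_modulus_bar_nm3 < 0
        )
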