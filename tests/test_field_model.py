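"""Field-model unit and property tests.

The disc solid angle has a hand-checkable on-axis closed form and an
independent adaptive-quadrature route; the mid-plane density inherits
axisymmetry, a thin-gap (parallel-plate) limit, current conservation
across the mid-plane, and monotone radial decay.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paddle_ire.errors import DomainError, InputError, PrecisionError
from paddle_ire.field_model import (
    MidplaneModel,
    PaddleGeometry,
    RadialGrid,
    disc_solid_angle,
    midplane_flux,
    nominal_midplane_density,
    nominal_profile,
    read_profile,
    scale_profile,
    write_profile,
)

A = 12.5  # default paddle radius, mm


class TestDiscSolidAngle:
    def test_on_axis_closed_form(self):
        # point at one radius distance on the axis: 2*pi*(1 - 1/sqrt(2))
        expected = 2 * math.pi * (1 - 1 / math.sqrt(2))
        assert disc_solid_angle(0.0, A, A) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.8403, abs=1e-4)

    def test_touching_point_sees_half_space(self):
        assert disc_solid_angle(0.0, 1e-9, A) == pytest.approx(2 * math.pi, rel=1e-6)

    def test_far_field_vanishes(self):
        assert disc_solid_angle(1e6, 3.5, A) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 5.0, 12.4, 12.5, 12.6, 20.0, 60.0])
    @pytest.mark.parametrize("d", [0.05, 2.0, 3.5, 6.0, 25.0])
    def test_elliptic_agrees_with_quadrature(self, rho, d):
        e = disc_solid_angle(rho, d, A, method="elliptic")
        q = disc_solid_angle(rho, d, A, method="quad")
        assert e == pytest.approx(q, rel=1e-8)
        assert 0.0 <= e < 2 * math.pi + 1e-12

    @given(
        rho=st.floats(0, 100),
        d=st.floats(0.01, 50),
        a=st.floats(0.5, 30),
    )
    @settings(max_examples=150, deadline=None)
    def test_bounds_property(self, rho, d, a):
        omega = disc_solid_angle(rho, d, a)
        assert 0.0 <= omega <= 2 * math.pi

    @pytest.mark.parametrize(
        "rho,d,a", [(1.0, 0.0, 5.0), (1.0, -2.0, 5.0), (1.0, 2.0, 0.0), (-1.0, 2.0, 5.0)]
    )
    def test_degenerate_geometry_raises(self, rho, d, a):
        with pytest.raises(DomainError):
            disc_solid_angle(rho, d, a)


class TestMidplaneDensity:
    def test_thin_gap_limit(self):
        # h << a: each disc subtends 2*pi, density -> 1/(pi a^2) = 0.2037 A/cm^2
        geom = PaddleGeometry(paddle_radius=A, separation=0.01)
        expected = 1.0 / (math.pi * 1.25**2)
        assert nominal_midplane_density(geom, 0.0) == pytest.approx(expected, rel=1e-3)

    def test_thin_gap_convergence_rate(self):
        # within 1% already at h = a/50
        geom = PaddleGeometry(paddle_radius=A, separation=A / 50)
        expected = 1.0 / (math.pi * 1.25**2)
        assert abs(nominal_midplane_density(geom, 0.0) - expected) / expected < 0.01

    def test_axisymmetry_mirror(self, geometry_h7):
        for x in (0.0, 1.7, 8.0, 25.0):
            assert nominal_midplane_density(geometry_h7, x) == nominal_midplane_density(
                geometry_h7, -x
            )

    def test_invalid_geometry(self):
        with pytest.raises(DomainError):
            PaddleGeometry(paddle_radius=-1.0, separation=7.0)
        with pytest.raises(DomainError):
            PaddleGeometry(paddle_radius=A, separation=0.0)


class TestProfiles:
    def test_single_point_grid(self, geometry_h7):
        prof = nominal_profile(geometry_h7, RadialGrid((0.0,)))
        assert prof.density[0] == nominal_midplane_density(geometry_h7, 0.0)

    def test_lookup_mode_rounds_to_whole_mm(self):
        cont = nominal_profile(
            PaddleGeometry(separation=7.0), RadialGrid.regular(10, 1.0), "continuous"
        )
        lut = nominal_profile(
            PaddleGeometry(separation=7.3), RadialGrid.regular(10, 1.0), "lookup"
        )
        assert lut.density == cont.density
        # banker's rounding on the half-millimetre
        assert nominal_profile(
            PaddleGeometry(separation=7.5), RadialGrid.regular(2, 1.0), "lookup"
        ).geometry.separation == 8.0
        assert nominal_profile(
            PaddleGeometry(separation=6.5), RadialGrid.regular(2, 1.0), "lookup"
        ).geometry.separation == 6.0

    @pytest.mark.parametrize("h_over_a", [0.3, 0.56, 1.0])
    def test_monotone_decay(self, h_over_a):
        geom = PaddleGeometry(paddle_radius=A, separation=h_over_a * A)
        prof = nominal_profile(geom, RadialGrid.regular(3 * A, 0.25))
        diffs = np.diff(prof.density_array())
        assert np.all(diffs <= 1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            RadialGrid(())

    def test_grid_must_start_at_zero_and_increase(self):
        with pytest.raises(InputError):
            RadialGrid((1.0, 2.0))
        with pytest.raises(InputError):
            RadialGrid((0.0, 2.0, 2.0))


class TestScaling:
    def test_zero_current_zeroes_profile(self, geometry_h7):
        prof = nominal_profile(geometry_h7, RadialGrid.regular(10, 1.0))
        assert np.all(scale_profile(prof, 0.0).density_array() == 0.0)

    def test_unit_current_is_identity(self, geometry_h7):
        prof = nominal_profile(geometry_h7, RadialGrid.regular(10, 1.0))
        np.testing.assert_array_equal(
            scale_profile(prof, 1.0).density_array(), prof.density_array()
        )

    def test_group_mean_current_scales_center(self, geometry_h7):
        # 25.3 A is the single-50J group mean peak current
        prof = nominal_profile(geometry_h7, RadialGrid.regular(10, 1.0))
        scaled = scale_profile(prof, 25.3)
        assert scaled.density_array()[0] == pytest.approx(25.3 * prof.density[0], rel=1e-15)

    def test_scaling_composes_exactly(self, geometry_h7):
        prof = nominal_profile(geometry_h7, RadialGrid.regular(5, 1.0))
        once = scale_profile(prof, 2.5 * 4.0).density_array()
        twice = scale_profile(prof, 2.5).density_array() * 4.0
        np.testing.assert_array_equal(once, twice)

    def test_negative_current_rejected(self, geometry_h7):
        prof = nominal_profile(geometry_h7, RadialGrid.regular(5, 1.0))
        with pytest.raises(InputError):
            scale_profile(prof, -1.0)


class TestMidplaneFlux:
    @pytest.mark.parametrize("h", [4.0, 7.0, 12.0])
    def test_unit_current_conservation(self, h):
        geom = PaddleGeometry(paddle_radius=A, separation=h)
        prof = nominal_profile(geom, RadialGrid.regular(100.0, 0.25))
        assert midplane_flux(prof) == pytest.approx(1.0, abs=0.01)

    def test_scaled_flux_is_linear(self, geometry_h7):
        # 22.4 A is the serial-group mean peak current
        prof = nominal_profile(geometry_h7, RadialGrid.regular(100.0, 0.5))
        assert midplane_flux(scale_profile(prof, 22.4)) == pytest.approx(22.4, abs=0.3)

    def test_short_grid_raises_precision_error(self, geometry_h7):
        prof = nominal_profile(geometry_h7, RadialGrid.regular(20.0, 0.5))
        with pytest.raises(PrecisionError):
            midplane_flux(prof)  # tail fraction 7/(2*20) = 17.5%


class TestLesionHalfwidthInversion:
    def test_round_trip(self, model):
        hw = model.lesion_halfwidth(7.0, 22.4, 2.0)
        assert hw > 0
        assert model.delivered(7.0, hw, 22.4) == pytest.approx(2.0, rel=1e-9)

    def test_no_lesion_when_center_below_threshold(self, model):
        center = model.delivered(7.0, 0.0, 22.4)
        assert model.lesion_halfwidth(7.0, 22.4, center * 1.01) == 0.0


class TestProfileIO:
    def test_round_trip(self, geometry_h7, tmp_path):
        prof = nominal_profile(geometry_h7, RadialGrid.regular(10, 0.5))
        path = tmp_path / "profile.csv"
        write_profile(prof, path)
        back = read_profile(path)
        assert back.geometry == prof.geometry
        assert back.grid.offsets == prof.grid.offsets
        np.testing.assert_allclose(back.density_array(), prof.density_array(), rtol=1e-9)

    def test_missing_sidecar_rejected(self, geometry_h7, tmp_path):
        prof = nominal_profile(geometry_h7, RadialGrid.regular(5, 1.0))
        path = tmp_path / "profile.csv"
        write_profile(prof, path)
        path.with_suffix(".csv.json").unlink()
        with pytest.raises(InputError):
            read_profile(path)
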