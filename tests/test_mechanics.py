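"""Osmotic pressure, spheroid geometry, softening rigidity and the
quasi-static pressure balance."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from mitoswell import (Deformation, GeometryParams, MechanicsModel,
                       RigidityParams, SphericalRigidityParams,
                       ellipsoid_surface_area, ellipsoid_volume,
                       membrane_pressure, osmotic_pressure,
                       rigidity_component, solve_deformation,
                       spherical_volume_rate)


def surface_area_quadrature(a, c):
    """Independent surface-of-revolution quadrature for the spheroid."""
    def integrand(z):
        r = a * math.sqrt(max(1.0 - (z / c) ** 2, 0.0))
        if r == 0.0:
            return 0.0
        drdz = -a * z / (c * c * math.sqrt(1.0 - (z / c) ** 2))
        return 2.0 * math.pi * r * math.sqrt(1.0 + drdz * drdz)
    val, _ = quad(integrand, -c, c, limit=200, epsabs=1e-22, epsrel=1e-10)
    return val


class TestOsmoticPressure:
    def test_matched_activities(self, constants):
        assert osmotic_pressure([1.0, 2.0], [1.0, 2.0], constants) == 0.0

    def test_van_t_hoff_magnitude(self, constants):
        # 1 mM total activity excess at 310 K is ~2.577 kPa
        p = osmotic_pressure([1000.0], [0.0], constants)
        assert p == pytest.approx(2577.5, rel=1e-3)

    def test_additive_over_species(self, constants):
        p1 = osmotic_pressure([3.0], [1.0], constants)
        p2 = osmotic_pressure([0.5], [2.0], constants)
        both = osmotic_pressure([3.0, 0.5], [1.0, 2.0], constants)
        assert both == pytest.approx(p1 + p2)

    def test_misaligned_lists_rejected(self, constants):
        with pytest.raises(ValueError):
            osmotic_pressure([1.0], [1.0, 2.0], constants)


class TestSpheroidGeometry:
    def test_sphere_limit(self):
        g = GeometryParams(semi_a=1.0e-6, semi_c=1.0e-6 + 1e-18)
        s = ellipsoid_surface_area(g, Deformation(0.0, 0.0))
        assert s == pytest.approx(4 * math.pi * 1e-12, rel=1e-9)

    def test_default_area_against_quadrature(self, params):
        got = ellipsoid_surface_area(params.geometry, Deformation(0.0, 0.0))
        want = surface_area_quadrature(0.5e-6, 1.0e-6)
        assert got == pytest.approx(want, rel=1e-6)
        assert got * 1e12 == pytest.approx(5.3696, abs=2e-4)  # um^2

    @pytest.mark.parametrize("dx,dz", [(0.05e-6, 0.02e-6), (0.1e-6, 0.3e-6)])
    def test_deformed_area_against_quadrature(self, params, dx, dz):
        got = ellipsoid_surface_area(params.geometry, Deformation(dx, dz))
        want = surface_area_quadrature(0.5e-6 + dx, 1.0e-6 + dz)
        assert got == pytest.approx(want, rel=1e-6)

    def test_area_monotone_in_radial_deformation(self, params):
        dxs = np.linspace(0.0, 0.2e-6, 20)
        areas = [ellipsoid_surface_area(params.geometry, Deformation(dx, 0.0))
                 for dx in dxs]
        assert np.all(np.diff(areas) > 0)

    def test_oblate_branch_rejected(self, params):
        with pytest.raises(ValueError, match="prolate"):
            ellipsoid_surface_area(params.geometry,
                                   Deformation(0.6e-6, 0.0))

    def test_volume_formula(self, params):
        v0 = ellipsoid_volume(params.geometry, Deformation(0.0, 0.0))
        assert v0 * 1e18 == pytest.approx(math.pi / 3, rel=1e-12)
        # uniform 14.47% strain gives the +50% volume point
        s = 1.5 ** (1 / 3) - 1
        v = ellipsoid_volume(params.geometry,
                             Deformation(s * 0.5e-6, s * 1.0e-6))
        assert v / v0 == pytest.approx(1.5, rel=1e-12)


class TestRigidity:
    def test_undeformed_value(self):
        assert rigidity_component(0.0, 0.017, 1e6, 4) == pytest.approx(0.017)

    def test_vanishing_point_and_floor(self):
        beta, n1 = 2.0, 4.0
        delta_star = (1.0 / beta) ** (1 / n1)
        assert rigidity_component(delta_star, 1.0, beta, n1) \
            == pytest.approx(0.0, abs=1e-12)
        assert rigidity_component(2 * delta_star, 1.0, beta, n1) == 0.0

    def test_monotone_decreasing(self):
        deltas = np.linspace(0.0, 1.0, 50)
        gs = [rigidity_component(d, 1.0, 1.0, 4.0) for d in deltas]
        assert np.all(np.diff(gs) <= 0)


class TestMembranePressure:
    def test_zero_deformation(self):
        assert membrane_pressure(Deformation(0.0, 0.0), 1.0, 1.0, 1e-12) == 0.0

    def test_linear_in_deformation(self):
        p1 = membrane_pressure(Deformation(1e-8, 2e-8), 3.0, 4.0, 5e-12)
        p2 = membrane_pressure(Deformation(2e-8, 4e-8), 3.0, 4.0, 5e-12)
        assert p2 == pytest.approx(2 * p1)

    def test_direct_scalar_oracle(self):
        d = Deformation(10e-9, 20e-9)
        gxx, gzz = 170.0, 190.0  # table values in N/m
        s_m = 5.3696e-12
        want = (2 * gxx * 10e-9 + gzz * 20e-9) / s_m
        assert membrane_pressure(d, gxx, gzz, s_m) == pytest.approx(
            want, rel=1e-12)


class TestQuasiStaticBalance:
    def test_zero_pressure_zero_deformation(self, params):
        st = solve_deformation(0.0, params.geometry, params.rigidity,
                               params.normalization.rigidity_pressure_scale)
        assert st.deformation.dx == 0.0
        assert not st.irreversible

    def test_balance_consistency_below_ceiling(self, params):
        model = MechanicsModel(params.geometry, params.rigidity,
                               params.normalization.rigidity_pressure_scale)
        for frac in (0.1, 0.4, 0.7, 0.95):
            dp = frac * model.max_pressure
            st = model.solve(dp)
            assert not st.irreversible
            back = membrane_pressure(st.deformation, st.rigidity_xx,
                                     st.rigidity_zz, st.s_m)
            assert abs(back - dp) / dp < 1e-8
            assert st.deformation.dx / params.geometry.semi_a \
                < params.rigidity.crit_strain

    def test_above_ceiling_is_irreversible_at_critical_strain(self, params):
        model = MechanicsModel(params.geometry, params.rigidity,
                               params.normalization.rigidity_pressure_scale)
        st = model.solve(1.5 * model.max_pressure)
        assert st.irreversible
        strain = st.deformation.dx / params.geometry.semi_a
        assert strain == pytest.approx(params.rigidity.crit_strain)
        assert strain >= 0.144
        assert st.rigidity_xx == st.rigidity_zz == 0.0
        assert st.v_m / (4 / 3 * math.pi * 0.25e-12 * 1e-6) \
            == pytest.approx(1.5, rel=1e-6)

    def test_latch_persists(self, params):
        model = MechanicsModel(params.geometry, params.rigidity,
                               params.normalization.rigidity_pressure_scale)
        st = model.solve(0.1 * model.max_pressure, latched=True)
        assert st.irreversible
        assert st.rigidity_xx == 0.0
        assert st.dp_imm == 0.0

    def test_literal_softening_constants_vanish_almost_immediately(self):
        """Without recalibration the table betas zero the rigidity at
        sub-nanometer deformations, far below the critical strain."""
        rig = RigidityParams(recalibrate_beta=False)
        model = MechanicsModel(GeometryParams(), rig, pressure_scale=1.0)
        # rigidity is dead by 0.1 nm of radial deformation
        assert model._rigidities(0.1e-9 / 0.5e-6)[0] == 0.0


class TestSphericalModel:
    def test_fixed_point(self):
        p = SphericalRigidityParams(eta_w=1.0, kappa0=2.0)
        assert spherical_volume_rate(0.0, 0.0, p) == 0.0

    def test_linear_regime_matches_closed_form(self):
        eta, kappa = 0.8, 3.0
        p = SphericalRigidityParams(eta_w=eta, kappa0=kappa, gamma_soft=0.0)
        dp = 10.0
        sol = solve_ivp(lambda t, y: [spherical_volume_rate(dp, y[0], p)],
                        (0.0, 4.0), [0.0], rtol=1e-10, atol=1e-13,
                        dense_output=True)
        for t in (0.5, 1.0, 2.0, 4.0):
            want = eta / kappa * dp * (1 - math.exp(-kappa * t))
            assert sol.sol(t)[0] == pytest.approx(want, rel=1e-7)

    def test_softening_disabled_equals_linear_law(self):
        p = SphericalRigidityParams(eta_w=1.0, kappa0=2.0, gamma_soft=0.0)
        assert spherical_volume_rate(5.0, 3.0, p) == pytest.approx(
            1.0 * 5.0 - 2.0 * 3.0)

    def test_softening_reduces_restoring_term(self):
        soft = SphericalRigidityParams(eta_w=0.0, kappa0=2.0,
                                       gamma_soft=0.5, m_soft=1.0)
        hard = SphericalRigidityParams(eta_w=0.0, kappa0=2.0, gamma_soft=0.0)
        assert spherical_volume_rate(0.0, 1.0, soft) \
            > spherical_volume_rate(0.0, 1.0, hard)
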