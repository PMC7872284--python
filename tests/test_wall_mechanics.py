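"""Viscous-shell mechanics: tensions, strain rates, velocities, thickness."""

import numpy as np
import pytest

from shmoo.geometry import AxisymShape, make_sphere
from shmoo.wall_mechanics import (MechanicsParams, advance_shape,
                                  solve_tensions, solve_wall_fields,
                                  strain_rates_from_tensions,
                                  surface_velocities, thickness_flux_audit,
                                  update_thickness, viscosity_profile)


class TestTensions:
    def test_laplace_law_on_sphere(self, sphere):
        ss, sp = solve_tensions(sphere, 0.2)
        assert np.allclose(ss, 0.2 * 2.0 / 2.0, rtol=0, atol=1e-15)
        assert np.allclose(sp, 0.2 * 2.0 / 2.0, rtol=0, atol=1e-15)

    def test_cylinder_tensions(self, open_cylinder):
        ss, sp = solve_tensions(open_cylinder, 1.0)
        assert np.allclose(ss, 0.5)
        assert np.allclose(sp, 1.0)

    def test_pointwise_substitution(self):
        sh = AxisymShape(s=np.array([0.0, 1.0]), r=np.array([0.0, 1.0]),
                         z=np.array([0.0, -1.0]), theta=np.array([0.0, 1.0]),
                         kappa_s=np.array([0.5, 0.5]),
                         kappa_phi=np.array([1.0, 1.0]),
                         h=np.array([0.1, 0.1]))
        ss, sp = solve_tensions(sh, 1.0)
        assert ss[0] == pytest.approx(0.5)
        assert sp[0] == pytest.approx(0.75)

    def test_tensions_ignore_viscosity_and_thickness(self, sphere):
        ss1, sp1 = solve_tensions(sphere, 0.2)
        other = sphere.copy()
        other.h = other.h * 17.0
        ss2, sp2 = solve_tensions(other, 0.2)
        assert np.array_equal(ss1, ss2) and np.array_equal(sp1, sp2)


class TestStrainRates:
    def test_isotropic_tension(self):
        es, ep = strain_rates_from_tensions(3.0, 3.0, 2.0, 0.5)
        assert es == pytest.approx(3.0 / 6.0)
        assert ep == pytest.approx(3.0 / 6.0)

    def test_zero_meridional_rate_when_hoop_double(self):
        es, ep = strain_rates_from_tensions(1.0, 2.0, 1.0, 1.0)
        assert es == pytest.approx(0.0)

    def test_roundtrip_inverts_constitutive_law(self):
        rng = np.random.default_rng(0)
        es, ep = rng.normal(size=50), rng.normal(size=50)
        mu, h = 7.0, 0.2
        ss = 4 * mu * h * (es + ep / 2)
        sp = 4 * mu * h * (es / 2 + ep)
        es2, ep2 = strain_rates_from_tensions(ss, sp, mu, h)
        assert np.allclose(es2, es, atol=1e-14)
        assert np.allclose(ep2, ep, atol=1e-14)


class TestViscosityProfile:
    @pytest.mark.parametrize("s,expected", [(0.0, 1.0), (0.7, np.e),
                                            (1.4, np.e ** 4)])
    def test_graded_exponential(self, s, expected):
        assert viscosity_profile(s, 1.0, 0.7) == pytest.approx(expected)

    def test_capped_far_from_tip(self):
        assert viscosity_profile(100.0, 2.0, 0.5) == pytest.approx(2.0e6)


class TestSurfaceVelocities:
    def test_uniform_inflation_of_sphere(self, sphere):
        c = 0.01
        n = sphere.n_nodes
        u, vn = surface_velocities(sphere, np.full(n, c), np.full(n, c))
        assert np.allclose(u, 0.0, atol=1e-10)
        assert np.allclose(vn, c * 2.0, atol=1e-10)

    def test_rigid_state(self, sphere):
        n = sphere.n_nodes
        u, vn = surface_velocities(sphere, np.zeros(n), np.zeros(n))
        assert np.allclose(u, 0.0, atol=1e-14)
        assert np.allclose(vn, 0.0, atol=1e-14)

    def test_axial_stretching_of_cylinder(self, open_cylinder):
        c = 0.02
        n = open_cylinder.n_nodes
        u, vn = surface_velocities(open_cylinder, np.full(n, c), np.zeros(n))
        assert np.allclose(u, c * open_cylinder.s, rtol=1e-8, atol=1e-10)
        assert np.allclose(vn, 0.0, atol=1e-10)


class TestUpdateThickness:
    def test_pure_deposition(self, sphere):
        g, dt = 0.003, 0.5
        h = update_thickness(sphere, np.zeros(sphere.n_nodes),
                             np.full(sphere.n_nodes, g), dt)
        assert np.allclose(h, sphere.h + g * dt, atol=1e-14)

    def test_no_flux_no_deposition_leaves_h(self, sphere):
        h = update_thickness(sphere, np.zeros(sphere.n_nodes),
                             np.zeros(sphere.n_nodes), 1.0)
        assert np.allclose(h, sphere.h)

    def test_discrete_conservation_audit(self, projection):
        rng = np.random.default_rng(1)
        n = projection.n_nodes
        u = 0.01 * np.sin(np.linspace(0, np.pi, n))
        G = 0.001 * rng.random(n)
        dt = 0.05
        h_new = update_thickness(projection, u, G, dt)
        resid = thickness_flux_audit(projection, projection.h, h_new, u, G, dt)
        assert resid < 1e-6


class TestAdvanceShape:
    def test_zero_velocity_identity(self, sphere):
        n = sphere.n_nodes
        out = advance_shape(sphere, np.zeros(n), np.zeros(n), 1.0)
        assert np.allclose(out.r, sphere.r, atol=1e-8)
        assert np.allclose(out.z, sphere.z, atol=1e-8)

    def test_uniform_inflation_gives_larger_sphere(self, sphere):
        c, dt = 0.01, 0.1
        n = sphere.n_nodes
        vn = np.full(n, c * 2.0)
        out = advance_shape(sphere, np.zeros(n), vn, dt)
        R_new = 0.5 * (out.z[0] - out.z[-1])
        assert R_new == pytest.approx(2.0 * (1 + c * dt), rel=1e-6)

    def test_tip_localized_growth_moves_tip(self, projection):
        n = projection.n_nodes
        vn = 0.01 * np.exp(-projection.s ** 2 / 0.25)
        out = advance_shape(projection, np.zeros(n), vn, 1.0)
        assert out.z[0] > projection.z[0]


class TestFullPipeline:
    def test_expansion_localized_at_tip(self, projection):
        wf = solve_wall_fields(projection, MechanicsParams())
        er = wf.expansion_rate
        assert np.argmax(er) == 0
        lam = MechanicsParams().lambda_A
        # window starts past the cap/tube junction, where the fixture's
        # curvature discontinuity leaves a small tension bump
        mid = (projection.s > 1.8 * lam) & (projection.s < 3 * lam)
        # strictly decaying through the graded zone ...
        assert np.all(np.diff(er[mid]) < 0)
        # ... and negligible beyond it (solid-like wall)
        assert np.all(er[projection.s > 3 * lam] < 1e-3 * er[0])

    def test_apex_tangential_velocity_vanishes(self, projection):
        wf = solve_wall_fields(projection, MechanicsParams())
        assert wf.u[0] == pytest.approx(0.0, abs=1e-12)

    def test_distal_wall_anchored(self, projection):
        wf = solve_wall_fields(projection, MechanicsParams())
        assert abs(wf.v_n[-1]) < 1e-3 * abs(wf.v_n[0])

    def test_positive_parameters_enforced(self):
        with pytest.raises(ValueError):
            MechanicsParams(P=-1.0)
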