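"""Solid-sphere elastostatics: closed forms, invariants, inverse problem."""

import numpy as np
import pytest

from mptfm._sphharm import RealSHBasis, n_modes
from mptfm.elasticity import (
    CostBreakdown,
    ElasticBody,
    VectorFieldSH,
    cost_terms,
    decompose_stress,
    forward_solve,
    infer_tractions,
    integrate_region_force,
    mode_matrices,
    traction_map_from_field,
    traction_to_displacement,
)
from mptfm.synthetic import forward_displace_mesh, make_synthetic_traction

R, E = 3.7, 1400.0


def uniform_radial_field(lmax, value_um):
    """u_r = value everywhere (coefficient of the constant harmonic)."""
    u = VectorFieldSH.zeros(lmax)
    u.radial[0] = value_um * np.sqrt(4.0 * np.pi)
    return u


class TestForwardSolve:
    @pytest.mark.parametrize("nu", [0.3, 0.45, 0.49])
    def test_uniform_pressure_closed_form(self, nu):
        """u_r = -p R (1 - 2 nu) / E produces uniform normal traction -p."""
        body = ElasticBody(R, E, nu)
        p = 100.0
        u = uniform_radial_field(4, -p * R * (1.0 - 2.0 * nu) / E)
        t = forward_solve(u, body)
        basis = RealSHBasis.gauss_legendre(4, 10, 20)
        t_r, t_t, t_p = t.synth(basis)
        assert np.abs(t_r + p).max() < 0.01 * p
        assert np.abs(t_t).max() < 1e-10 * p
        assert np.abs(t_p).max() < 1e-10 * p

    def test_rigid_modes_zero_traction(self, body):
        """Rigid translations and rotations carry no traction."""
        c = np.sqrt(4.0 * np.pi / 3.0)
        u = VectorFieldSH.zeros(4)
        u.radial[2] = c  # translation along z: u_r = cos(theta)
        u.spheroidal[2] = c
        assert forward_solve(u, body).l2_norm() <= 1e-10 * E
        w = VectorFieldSH.zeros(4)
        w.toroidal[1:4] = 1.0  # the three rigid rotations
        assert forward_solve(w, body).l2_norm() <= 1e-10 * E

    def test_linearity(self, body):
        rng = np.random.default_rng(0)
        u1, u2 = VectorFieldSH.zeros(6), VectorFieldSH.zeros(6)
        for u in (u1, u2):
            u.radial = rng.standard_normal(n_modes(6)) * 0.01
            u.spheroidal = rng.standard_normal(n_modes(6)) * 0.01
            u.toroidal = rng.standard_normal(n_modes(6)) * 0.01
        t12 = forward_solve(u1 + u2, body)
        tsum = forward_solve(u1, body) + forward_solve(u2, body)
        d = t12 + (-1.0) * tsum
        assert d.l2_norm() < 1e-12 * max(tsum.l2_norm(), 1.0)

    @pytest.mark.parametrize("l", [2, 5, 10])
    def test_degree_diagonality(self, body, l):
        """A pure degree-l displacement yields a pure degree-l traction."""
        u = VectorFieldSH.zeros(12)
        degs = u.degrees
        u.radial[degs == l] = 0.01
        u.spheroidal[degs == l] = 0.005
        u.toroidal[degs == l] = 0.003
        t = forward_solve(u, body)
        other = degs != l
        assert np.abs(t.radial[other]).max() == 0.0
        assert np.abs(t.spheroidal[other]).max() == 0.0
        assert np.abs(t.toroidal[other]).max() == 0.0

    def test_reciprocity_of_per_degree_blocks(self, body):
        """Betti reciprocity: diag(1, l(l+1)) M_l is symmetric."""
        Ms, _ = mode_matrices(10, body)
        for l in range(1, 11):
            K = np.diag([1.0, l * (l + 1.0)]) @ Ms[l]
            assert abs(K[0, 1] - K[1, 0]) < 1e-10 * np.abs(K).max()

    def test_nu_half_rejected(self):
        with pytest.raises(ValueError, match="0.499"):
            ElasticBody(R, E, 0.5)

    def test_inverse_of_forward(self, body):
        rng = np.random.default_rng(3)
        u = VectorFieldSH.zeros(8)
        u.radial = rng.standard_normal(n_modes(8)) * 0.01
        u.spheroidal = rng.standard_normal(n_modes(8)) * 0.01
        u.toroidal = rng.standard_normal(n_modes(8)) * 0.01
        degs = u.degrees
        for f in (u.radial, u.spheroidal, u.toroidal):
            f[degs < 2] = 0.0
        back = traction_to_displacement(forward_solve(u, body), body)
        d = back + (-1.0) * u
        assert d.l2_norm() < 1e-10 * u.l2_norm()


class TestCostTerms:
    def test_zero_traction_all_zero(self, body):
        u = VectorFieldSH.zeros(6)
        t = VectorFieldSH.zeros(6)
        c = cost_terms(u, t, body)
        assert c.E_el == 0.0 and c.R2 == 0.0 and c.E_pen == 0.0 and c.total == 0.0

    def test_traction_inside_mask_gives_zero_residual(self, body):
        t = make_synthetic_traction(4, 50.0, seed=0, body=body)
        u = traction_to_displacement(t, body)
        c = cost_terms(u, t, body, mask=lambda th, ph: np.ones_like(th, bool))
        assert c.R2 == 0.0
        assert c.E_el > 0.0

    def test_quadratic_scaling(self, body):
        t = make_synthetic_traction(4, 50.0, seed=1, body=body)
        u = traction_to_displacement(t, body)
        outside_half = lambda th, ph: th < np.pi / 2
        c1 = cost_terms(u, t, body, mask=outside_half)
        c2 = cost_terms(u, 2.0 * t, body, mask=outside_half)
        assert c2.R2 == pytest.approx(4.0 * c1.R2, rel=1e-10)
        assert c2.E_pen == pytest.approx(4.0 * c1.E_pen, rel=1e-10)

    def test_mismatched_truncation_rejected(self, body):
        with pytest.raises(ValueError, match="truncation"):
            cost_terms(VectorFieldSH.zeros(4), VectorFieldSH.zeros(6), body)


class TestDecomposeStress:
    def test_pure_radial(self):
        n, s = decompose_stress(np.array([-100.0]), np.array([0.0]), np.array([0.0]))
        assert n[0] == -100.0 and s[0] == 0.0

    def test_pure_tangential(self):
        n, s = decompose_stress(np.array([0.0]), np.array([30.0]), np.array([40.0]))
        assert n[0] == 0.0 and s[0] == pytest.approx(50.0)

    def test_pythagoras_with_tilted_normals(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((3, 50))
        nvec = rng.standard_normal((3, 50))
        nvec /= np.linalg.norm(nvec, axis=0)
        n, s = decompose_stress(t[0], t[1], t[2], (nvec[0], nvec[1], nvec[2]))
        assert np.allclose(n**2 + s**2, (t**2).sum(axis=0))


class TestRegionForce:
    def test_uniform_cap_pressure_integrals(self, body):
        """100 Pa inward over a 30-degree cap: total 2 pi R^2 (1-cos a) p,
        net axial pi (R sin a)^2 p."""
        basis_map = traction_map_from_field(
            VectorFieldSH.zeros(2), body, "gl", 400, 40
        )
        th = basis_map.theta[:, None] * np.ones_like(basis_map.phi)[None, :]
        cap = th < np.radians(30.0)
        tmap = basis_map
        tmap.t_r = np.where(cap, -100.0, 0.0)
        tmap.t_theta = np.zeros_like(tmap.t_r)
        tmap.t_phi = np.zeros_like(tmap.t_r)
        f = integrate_region_force(tmap, cap)
        expected_total = 100.0 * 2 * np.pi * R**2 * (1 - np.cos(np.radians(30)))
        expected_net_z = -100.0 * np.pi * (R * np.sin(np.radians(30))) ** 2
        assert f.total_unsigned_pN == pytest.approx(expected_total, rel=0.02)
        assert f.net_pN[2] == pytest.approx(expected_net_z, rel=0.02)
        assert abs(f.net_pN[0]) < 1e-9 and abs(f.net_pN[1]) < 1e-9

    def test_zero_field(self, body):
        tmap = traction_map_from_field(VectorFieldSH.zeros(2), body, "gl", 20, 40)
        f = integrate_region_force(tmap)
        assert f.total_unsigned_pN == 0.0 and f.net_magnitude_pN == 0.0

    def test_empty_region_rejected(self, body):
        tmap = traction_map_from_field(VectorFieldSH.zeros(2), body, "gl", 20, 40)
        with pytest.raises(ValueError, match="empty"):
            integrate_region_force(tmap, lambda th, ph: np.zeros_like(th, bool))

    def test_equilibrium_field_has_no_net_force(self, body):
        t = make_synthetic_traction(6, 100.0, seed=2, body=body)
        tmap = traction_map_from_field(t, body, "gl", 32, 64)
        f = integrate_region_force(tmap)
        assert f.net_magnitude_pN <= 0.01 * f.total_unsigned_pN


class TestInference:
    def test_undeformed_sphere_zero_traction(self, sphere_mesh, body):
        res = infer_tractions(sphere_mesh, body, lmax=10)
        assert np.abs(res.tmap.t_r).max() <= 1e-6 * E
        assert np.abs(res.tmap.shear).max() <= 1e-6 * E

    def test_round_trip_small(self, body):
        """Quick low-degree round trip; the acceptance suite runs the full one."""
        t_true = make_synthetic_traction(5, 150.0, seed=4, body=body)
        mesh = forward_displace_mesh(t_true, body, n_directions=2000)
        res = infer_tractions(mesh, body, lmax=12, n_theta=32, n_phi=64)
        tt = VectorFieldSH.zeros(12)
        n = t_true.radial.size
        tt.radial[:n] = t_true.radial
        tt.spheroidal[:n] = t_true.spheroidal
        tt.toroidal[:n] = t_true.toroidal
        d = res.traction + (-1.0) * tt
        assert d.l2_norm() / tt.l2_norm() < 0.15

    def test_translation_invariance(self, body):
        t_true = make_synthetic_traction(5, 150.0, seed=5, body=body)
        mesh = forward_displace_mesh(t_true, body, n_directions=2000)
        res1 = infer_tractions(mesh, body, lmax=10, n_theta=28, n_phi=56)
        shifted = type(mesh)(
            mesh.vertices + np.array([0.05, -0.02, 0.03]),
            mesh.faces.copy(),
            mesh.center + np.array([0.05, -0.02, 0.03]),
        )
        res2 = infer_tractions(shifted, body, lmax=10, n_theta=28, n_phi=56)
        d = res1.traction + (-1.0) * res2.traction
        assert d.l2_norm() < 1e-6 * res1.traction.l2_norm()

    def test_tractions_scale_with_modulus(self, body):
        t_true = make_synthetic_traction(4, 100.0, seed=6, body=body)
        mesh = forward_displace_mesh(t_true, body, n_directions=2000)
        res1 = infer_tractions(mesh, body, lmax=8, n_theta=24, n_phi=48)
        stiff = ElasticBody(body.radius, 2.0 * body.youngs_modulus, body.poisson)
        res2 = infer_tractions(mesh, stiff, lmax=8, n_theta=24, n_phi=48)
        d = res2.traction + (-2.0) * res1.traction
        assert d.l2_norm() < 1e-9 * res2.traction.l2_norm()

    def test_large_deformation_rejected(self, body):
        t_true = make_synthetic_traction(4, 100.0, seed=7, body=body)
        mesh = forward_displace_mesh(t_true, body, n_directions=500)
        big = type(mesh)(
            mesh.center + (mesh.vertices - mesh.center) * 1.2,
            mesh.faces.copy(),
            mesh.center,
        )
        with pytest.raises(ValueError, match="small-strain"):
            infer_tractions(big, body, lmax=6)

    def test_cost_breakdown_consistency(self):
        c = CostBreakdown(1.0, 2.0, 3.0, alpha=1.0, beta=1.0)
        assert c.total == 6.0
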