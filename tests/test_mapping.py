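"""Surface mapping, engulfment masks, cup alignment and metrics."""

import numpy as np
import pytest

from mptfm import mapping
from mptfm.geometry import fibonacci_directions
from mptfm.mesh import SurfaceMesh
from mptfm.synthetic import (
    RingGroove,
    SceneSpec,
    SurfaceSignal,
    make_cup_fixture,
    make_deformed_sphere,
    render_stack,
)

R = 3.7


class TestProjectSurfaceIntensity:
    def test_uniform_shell_uniform_within_colatitude_ring(self, sphere_mesh, sphere_spec):
        """Projection of a uniform shell is azimuthally uniform; the
        anisotropic PSF (wider along z) lowers absolute values toward the
        poles, so uniformity is asserted per colatitude ring."""
        st = render_stack(sphere_mesh, sphere_spec, "surface")
        vals = mapping.project_surface_intensity(st, sphere_mesh)
        th, _ = sphere_mesh.angles
        ring = (th > 1.4) & (th < 1.7)
        assert vals[ring].std() / vals[ring].mean() < 0.05
        assert vals.min() > 0.0

    def test_window_excludes_distant_signal(self, sphere_mesh, sphere_spec):
        """A shell 2 um outside the surface is beyond the 1 um window."""
        far = SurfaceMesh(
            sphere_mesh.center + (sphere_mesh.vertices - sphere_mesh.center) * (R + 2.0) / R,
            sphere_mesh.faces.copy(),
            sphere_mesh.center,
        )
        st = render_stack(far, sphere_spec, "surface")
        near_vals = mapping.project_surface_intensity(st, sphere_mesh)
        on_vals = mapping.project_surface_intensity(st, far)
        assert near_vals.max() < 0.5 * on_vals.max()

    def test_spot_amplitude_recovered(self, cup_bundle):
        b = cup_bundle
        st = render_stack(b.mesh, SceneSpec(), "surface", surface_amplitude=b.actin_signal)
        vals = mapping.project_surface_intensity(st, b.mesh)
        # band+spot peak is ~300 before the PSF spreads the thin shell
        assert vals.max() > 50.0
        assert vals.max() > 3.0 * np.median(vals)


class TestContactMask:
    def test_fixture_mask_matches_truth(self, cup_bundle):
        b = cup_bundle
        mask = mapping.compute_contact_mask(b.mesh, b.vertex_exposed, b.vertex_actin)
        jac = (mask & b.truth_mask).sum() / (mask | b.truth_mask).sum()
        assert jac >= 0.95

    def test_uniformly_high_exposed_empty_mask(self, sphere_mesh):
        n = len(sphere_mesh.vertices)
        mask = mapping.compute_contact_mask(
            sphere_mesh, np.full(n, 100.0), np.zeros(n)
        )
        assert not mask.any()
        assert mapping.fraction_engulfed(sphere_mesh, mask) == 0.0

    def test_zero_exposed_full_mask(self, sphere_mesh):
        n = len(sphere_mesh.vertices)
        mask = mapping.compute_contact_mask(sphere_mesh, np.zeros(n), np.zeros(n))
        assert mask.all()
        assert mapping.fraction_engulfed(sphere_mesh, mask) == 1.0


class TestFractionEngulfed:
    def test_hemisphere(self, sphere_mesh):
        th, _ = sphere_mesh.angles
        assert mapping.fraction_engulfed(sphere_mesh, th >= np.pi / 2) == pytest.approx(
            0.5, abs=0.01
        )

    def test_sixty_degree_cap(self, sphere_mesh):
        th, _ = sphere_mesh.angles
        cap = th >= np.pi - np.radians(60)
        assert mapping.fraction_engulfed(sphere_mesh, cap) == pytest.approx(0.25, abs=0.01)

    def test_resolution_invariance(self):
        for n in (1500, 3000):
            mesh = make_deformed_sphere(SceneSpec(radius_um=R, n_directions=n))
            th, _ = mesh.angles
            f = mapping.fraction_engulfed(mesh, th >= np.pi / 2)
            assert f == pytest.approx(0.5, abs=0.01)


class TestAlignment:
    def test_polar_cap_axis_recovered(self, aligned_cup, cup_bundle):
        err = np.degrees(
            np.arccos(np.clip(np.dot(aligned_cup.axis, cup_bundle.axis), -1, 1))
        )
        assert err <= 2.0

    def test_rotation_equivariance(self, cup_bundle):
        from mptfm.geometry import rotation_to_z

        b = cup_bundle
        Rm = rotation_to_z(np.array([1.0, 2.0, 3.0]) / np.sqrt(14.0))
        rotated = SurfaceMesh(b.mesh.vertices @ Rm.T, b.mesh.faces.copy(), np.zeros(3))
        cup0 = mapping.align_to_axis(b.mesh, b.truth_mask)
        cup1 = mapping.align_to_axis(rotated, b.truth_mask)
        # aligned frames agree up to an (arbitrary) azimuth about the axis
        th0, _ = cup0.mesh.angles
        th1, _ = cup1.mesh.angles
        assert np.allclose(th1, th0, atol=1e-9)
        assert np.allclose(cup1.mesh.radii, cup0.mesh.radii, atol=1e-9)
        assert np.allclose(cup1.x, cup0.x, atol=1e-9)
        assert cup1.fraction_engulfed == pytest.approx(cup0.fraction_engulfed)

    def test_rim_vertices_at_unit_position(self, aligned_cup):
        x_rim = aligned_cup.x[aligned_cup.boundary_vertices]
        assert x_rim.mean() == pytest.approx(1.0, abs=0.05)

    def test_empty_mask_requires_override(self, sphere_mesh):
        n = len(sphere_mesh.vertices)
        with pytest.raises(ValueError, match="override"):
            mapping.align_to_axis(sphere_mesh, np.zeros(n, bool))
        cup = mapping.align_to_axis(
            sphere_mesh, np.zeros(n, bool), axis_override=[0, 0, 1.0]
        )
        assert cup.fraction_engulfed == 0.0


class TestAxialProfiles:
    def test_uniform_signal_uniform_bins(self, aligned_cup):
        cup = aligned_cup
        cup2 = mapping.CupFrame(
            cup.mesh, cup.contact_mask, cup.axis, cup.fraction_engulfed,
            cup.x, cup.alpha_rim, signals={"flat": np.ones(len(cup.mesh.vertices))},
        )
        prof = mapping.axial_profiles(cup2)
        flat = prof.intensity["flat"][~prof.empty]
        assert np.allclose(flat, 1.0)

    def test_band_at_080_lands_in_correct_bin(self):
        spec = SceneSpec(surface_signal=SurfaceSignal(band_center_x=0.8))
        b = make_cup_fixture(0.5, 0, spec)
        mask = mapping.compute_contact_mask(b.mesh, b.vertex_exposed, b.vertex_actin)
        cup = mapping.align_to_axis(b.mesh, mask, signals={"actin": b.vertex_actin})
        prof = mapping.axial_profiles(cup)
        k = np.nanargmax(np.where(prof.empty, np.nan, prof.intensity["actin"]))
        bin_width = prof.x_centers[1] - prof.x_centers[0]
        assert abs(prof.x_centers[k] - 0.8) <= 1.5 * bin_width

    def test_sphere_radius_profile_constant(self, aligned_cup):
        prof = mapping.axial_profiles(aligned_cup)
        r = prof.radius_um[~prof.empty]
        # teeth dimples perturb the rim bins only slightly
        assert np.abs(r - R).max() < 0.1


class TestConstriction:
    def aligned_hemisphere(self, mesh):
        th, _ = mesh.angles
        return mapping.align_to_axis(mesh, th >= np.pi / 2, signals={})

    def test_sphere_has_no_constriction(self, sphere_mesh):
        cup = self.aligned_hemisphere(sphere_mesh)
        cup.mesh.compute_vertex_fields()
        prof = mapping.axial_profiles(cup)
        res = mapping.constriction_metrics(prof)
        assert res.constriction_um == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("depth", [0.05, 0.2, 0.4])
    def test_ring_groove_depth_recovered(self, depth):
        spec = SceneSpec(radius_um=R, rings=(RingGroove(np.pi / 2, 0.5, depth),))
        mesh = make_deformed_sphere(spec)
        mesh.compute_vertex_fields()
        cup = self.aligned_hemisphere(mesh)
        prof = mapping.axial_profiles(cup)
        res = mapping.constriction_metrics(prof)
        assert res.constriction_um == pytest.approx(depth, rel=0.15)
        assert res.location_x == pytest.approx(1.0, abs=0.1)

    def test_partial_azimuth_teeth_average_below_depth(self, aligned_cup):
        prof = mapping.axial_profiles(aligned_cup)
        res = mapping.constriction_metrics(prof)
        assert 0.0 < res.constriction_um < 0.2


class TestElongation:
    def test_sphere_zero(self, sphere_mesh):
        th, _ = sphere_mesh.angles
        cup = mapping.align_to_axis(sphere_mesh, th >= np.pi / 2)
        assert mapping.elongation(cup) == pytest.approx(0.0, abs=0.01)

    def test_prolate_spheroid(self):
        """Axes (1, 1, 1.2) R: elongation = 1.2 / 1.2^(1/3) - 1 ~ 0.129."""
        dirs = fibonacci_directions(3000)
        th = np.arccos(np.clip(dirs[:, 2], -1, 1))
        radii = R / np.sqrt(np.sin(th) ** 2 + np.cos(th) ** 2 / 1.2**2)
        mesh = SurfaceMesh.from_directions(dirs, radii)
        th2, _ = mesh.angles
        cup = mapping.align_to_axis(mesh, th2 >= np.pi / 2, axis_override=[0, 0, 1.0])
        expected = 1.2 / 1.2 ** (1 / 3) - 1.0
        assert mapping.elongation(cup) == pytest.approx(expected, abs=0.01)


class TestMollweide:
    def test_uniform_signal_uniform_map(self, aligned_cup):
        raster, inside = mapping.mollweide_map(
            aligned_cup, np.ones(len(aligned_cup.mesh.vertices))
        )
        assert np.nanstd(raster) == 0.0
        assert np.isnan(raster[~inside]).all()

    def test_integral_preserved(self, aligned_cup, cup_bundle):
        raster, inside = mapping.mollweide_map(aligned_cup, cup_bundle.vertex_actin)
        mesh = aligned_cup.mesh
        surface_mean = float(
            np.sum(cup_bundle.vertex_actin * mesh.vertex_areas) / mesh.area
        )
        assert np.nanmean(raster) == pytest.approx(surface_mean, rel=0.01)

    def test_pole_maps_to_vertical_center_edge(self, aligned_cup):
        th, _ = aligned_cup.mesh.angles
        signal = np.where(th < 0.1, 10.0, 0.0)  # +z pole spot
        raster, inside = mapping.mollweide_map(aligned_cup, signal, shape=(90, 180))
        ys, xs = np.where(raster > 5.0)
        # +z pole is latitude +pi/2: the high-y (last-row) apex of the ellipse
        assert ys.min() > 75
        assert abs(xs.mean() - 90) < 20  # horizontally centered
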