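"""Photometric-stereo unit and property tests."""

import numpy as np
import pytest

from hsskin.stereo import (
    GradientField,
    LightGeometry,
    frankot_chellappa,
    gradients_from_normals,
    light_direction_matrix,
    reconstruct_surface,
    solve_albedo_normals,
)

SQ3 = np.sqrt(3.0)


class TestLightMatrix:
    def test_default_geometry_matches_instrument_matrix(self):
        # 60 deg elevation, azimuths 90/330/210: the published center-field matrix
        L = light_direction_matrix(LightGeometry())
        expected = 0.5 * np.array(
            [[0, 1, SQ3], [SQ3 / 2, -0.5, SQ3], [-SQ3 / 2, -0.5, SQ3]]
        )
        np.testing.assert_allclose(L, expected, atol=1e-12)

    def test_rows_are_unit_vectors(self):
        L = light_direction_matrix(
            LightGeometry(elevation_deg=47.0, azimuths_deg=(10.0, 140.0, 260.0))
        )
        np.testing.assert_allclose(np.linalg.norm(L, axis=1), 1.0, atol=1e-12)

    def test_explicit_trigonometric_values(self):
        L = light_direction_matrix(
            LightGeometry(elevation_deg=60.0, azimuths_deg=(0.0, 120.0, 240.0))
        )
        expected = np.array(
            [
                [0.5, 0.0, SQ3 / 2],
                [-0.25, SQ3 / 4, SQ3 / 2],
                [-0.25, -SQ3 / 4, SQ3 / 2],
            ]
        )
        np.testing.assert_allclose(L, expected, atol=1e-12)

    def test_zenith_elevation_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            light_direction_matrix(LightGeometry(elevation_deg=90.0))

    def test_duplicate_azimuths_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            LightGeometry(azimuths_deg=(10.0, 10.0, 200.0))


class TestSolveAlbedoNormals:
    def setup_method(self):
        self.L = light_direction_matrix(LightGeometry())

    def test_flat_lambertian_surface(self):
        # upward normal under 60 deg lights: r_i = sqrt(3)/2 for all i
        r = np.full((5, 6), SQ3 / 2)
        nmap = solve_albedo_normals([r, r, r], self.L)
        np.testing.assert_allclose(nmap.albedo, 1.0, atol=1e-12)
        np.testing.assert_allclose(nmap.normals[..., 2], 1.0, atol=1e-12)
        assert not nmap.degenerate.any()

    def test_zero_reflectance_is_flagged(self):
        z = np.zeros((3, 3))
        nmap = solve_albedo_normals([z, z, z], self.L)
        assert nmap.degenerate.all()
        np.testing.assert_array_equal(nmap.albedo, 0.0)
        np.testing.assert_allclose(nmap.normals[..., 2], 1.0)

    def test_forward_model_recovery(self):
        rng = np.random.default_rng(7)
        a0 = rng.uniform(0.05, 1.0, (9, 9))
        n0 = rng.normal(size=(9, 9, 3))
        n0[..., 2] = np.abs(n0[..., 2]) + 1.2  # positive z, away from grazing
        n0 /= np.linalg.norm(n0, axis=-1, keepdims=True)
        refl = [a0 * (n0 @ self.L[i]) for i in range(3)]
        nmap = solve_albedo_normals(refl, self.L)
        assert np.abs(nmap.albedo[..., 0] - a0).max() < 1e-10
        assert np.abs(nmap.normals[:, :, 0, :] - n0).max() < 1e-10

    def test_shape_mismatch_names_offender(self):
        r = np.zeros((4, 4))
        with pytest.raises(ValueError, match="cube 2"):
            solve_albedo_normals([r, r, np.zeros((5, 4))], self.L)


class TestGradients:
    def test_flat_normal_gives_zero_gradients(self):
        n = np.zeros((2, 2, 3))
        n[..., 2] = 1.0
        g = gradients_from_normals(n)
        np.testing.assert_array_equal(g.p, 0.0)
        np.testing.assert_array_equal(g.q, 0.0)

    def test_printed_ratio_form(self):
        n = np.zeros((1, 1, 3))
        n[0, 0] = (0.6, 0.0, 0.8)
        g = gradients_from_normals(n)
        assert g.p[0, 0] == pytest.approx(0.75)
        assert g.q[0, 0] == pytest.approx(0.0)

    def test_grazing_normal_is_clamped(self):
        n = np.zeros((1, 1, 3))
        n[0, 0] = (0.0, 1.0, 0.0)
        g = gradients_from_normals(n, clamp_nz=0.01)
        assert g.q[0, 0] == pytest.approx(100.0)
        assert np.isfinite(g.q).all()

    def test_negate_flag_flips_sign(self):
        n = np.zeros((1, 1, 3))
        n[0, 0] = (0.6, 0.0, 0.8)
        g = gradients_from_normals(n, negate=True)
        assert g.p[0, 0] == pytest.approx(-0.75)


class TestFrankotChellappa:
    def test_zero_gradients_give_zero_depth(self):
        g = GradientField(p=np.zeros((8, 8)), q=np.zeros((8, 8)))
        np.testing.assert_array_equal(frankot_chellappa(g).Z, 0.0)

    def test_output_has_zero_mean(self):
        rng = np.random.default_rng(3)
        g = GradientField(p=rng.normal(size=(16, 12)), q=rng.normal(size=(16, 12)))
        assert frankot_chellappa(g).Z.mean() == pytest.approx(0.0, abs=1e-14)

    def test_recovers_closed_form_periodic_surface(self):
        H, W = 48, 64
        x = np.arange(W)[None, :]
        z = np.cos(2 * np.pi * x / W) * np.ones((H, 1))
        p = -2 * np.pi / W * np.sin(2 * np.pi * x / W) * np.ones((H, 1))
        Z = frankot_chellappa(GradientField(p=p, q=np.zeros((H, W))), epsilon=0.0).Z
        assert np.abs(Z - (z - z.mean())).max() < 1e-6

    def test_non_finite_input_rejected(self):
        p = np.zeros((4, 4))
        p[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            frankot_chellappa(GradientField(p=p, q=np.zeros((4, 4))))


def _render_triplet(height, albedo_scalar, L):
    """Noiseless Lambertian reflectances of a height map (test-local oracle)."""
    gy, gx = np.gradient(height)
    n = np.stack([-gx, -gy, np.ones_like(height)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return [albedo_scalar * np.maximum(n @ L[i], 0.0) for i in range(3)], n


class TestReconstructSurface:
    def setup_method(self):
        self.L = light_direction_matrix(LightGeometry())

    def test_hemisphere_depth_correlation(self):
        from hsskin.scenes import SceneSpec, make_height_map

        spec = SceneSpec(
            height_px=128, width_px=128, surface_kind="hemisphere",
            lesion_radius=40.0, lesion_class="bcc", noise_sd=0.0,
        )
        h = make_height_map(spec)
        refl, _ = _render_triplet(h, 0.7, self.L)
        _, depth = reconstruct_surface(refl, self.L)
        c = slice(32, 96)  # central 50 % crop
        corr = np.corrcoef(depth.Z[c, c].ravel(), h[c, c].ravel())[0, 1]
        assert corr > 0.95

    def test_reflectance_scaling_scales_albedo_not_depth(self):
        rng = np.random.default_rng(11)
        h = rng.normal(size=(32, 32))
        from scipy.ndimage import gaussian_filter

        h = gaussian_filter(h, 4.0) * 10
        refl, _ = _render_triplet(h, 0.5, self.L)
        nmap1, d1 = reconstruct_surface(refl, self.L)
        nmap2, d2 = reconstruct_surface([3.0 * r for r in refl], self.L)
        np.testing.assert_allclose(nmap2.albedo, 3.0 * nmap1.albedo, rtol=1e-10)
        np.testing.assert_allclose(d2.Z, d1.Z, atol=1e-10)

    def test_flat_scene_yields_flat_depth(self):
        refl, _ = _render_triplet(np.zeros((32, 32)), 0.8, self.L)
        _, depth = reconstruct_surface(refl, self.L)
        assert np.abs(depth.Z).max() < 1e-9

    def test_center_light_matrix_error_grows_toward_borders(self):
        # render with the true, spatially varying directions of point-source
        # LEDs at finite distance; reconstruct with the center-field matrix
        from hsskin.scenes import SceneSpec, make_height_map

        spec = SceneSpec(
            height_px=96, width_px=96, surface_kind="skin_lesion",
            lesion_radius=20.0, lesion_height=6.0, lesion_class="bcc",
            noise_sd=0.0,
        )
        h = make_height_map(spec)
        H, W = h.shape
        px_mm = 0.2
        dist, ring_r = 65.0, 33.0
        geom = LightGeometry()
        gy, gx = np.gradient(h)
        n = np.stack([-gx, -gy, np.ones_like(h)], axis=-1)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        pos = np.stack(
            [(xx - W / 2) * px_mm, (yy - H / 2) * px_mm, np.zeros_like(h)], axis=-1
        )
        refl = []
        for az in geom.azimuths_deg:
            phi = np.deg2rad(az)
            led = np.array([ring_r * np.cos(phi), ring_r * np.sin(phi), dist])
            v = led[None, None, :] - pos
            v /= np.linalg.norm(v, axis=-1, keepdims=True)
            refl.append(0.6 * np.maximum((n * v).sum(-1), 0.0))
        _, depth = reconstruct_surface(refl, light_direction_matrix(geom))
        err = depth.Z - (h - h.mean())
        c = slice(24, 72)
        # depth is defined up to a constant, so compare demeaned residuals
        rms = lambda a: float(np.sqrt(np.mean((a - a.mean()) ** 2)))
        assert rms(err[c, c]) < rms(err)

    def test_multiple_depth_wavelengths(self):
        refl, _ = _render_triplet(np.zeros((16, 16)), 0.5, self.L)
        cubes = [np.repeat(r[:, :, None], 3, axis=2) for r in refl]
        _, depths = reconstruct_surface(
            cubes, self.L, wavelengths=[500.0, 575.0, 700.0],
            depth_wavelength_nm=[575.0, 700.0],
        )
        assert [d.wavelength_nm for d in depths] == [575.0, 700.0]
        with pytest.raises(ValueError, match="not in grid"):
            reconstruct_surface(
                cubes, self.L, wavelengths=[500.0, 575.0, 700.0],
                depth_wavelength_nm=123.0,
            )
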