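"""Reflectance, band combination, spectral smoothing and ML preprocessing."""

import numpy as np
import pytest

from hsskin.preprocess import (
    FeatureStack,
    PROV_ORIGINAL,
    PROV_OVERSAMPLED,
    ReflectanceCube,
    SubCubeSet,
    augment_flips,
    balance_oversample,
    build_feature_stack,
    combine_vis_vnir,
    compute_reflectance,
    extract_windows,
    slice_half_sample,
    tv_denoise_spectral,
)
from hsskin.wavelengths import VIS_WAVELENGTHS_NM, VNIR_WAVELENGTHS_NM


class TestReflectance:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.W = rng.uniform(800, 1200, (6, 6, 4))
        self.D = rng.uniform(20, 60, (6, 6, 4))

    def test_white_target_reflects_one(self):
        out = compute_reflectance(self.W, self.W, self.D)
        np.testing.assert_allclose(out.values, 1.0)

    def test_dark_floor_reflects_zero(self):
        out = compute_reflectance(self.D, self.W, self.D)
        np.testing.assert_allclose(out.values, 0.0)

    def test_midpoint(self):
        R = 0.5 * (self.W - self.D) + self.D
        out = compute_reflectance(R, self.W, self.D)
        np.testing.assert_allclose(out.values, 0.5)

    def test_dead_reference_pixels_flagged_and_zeroed(self):
        W = self.W.copy()
        W[0, 0, :] = self.D[0, 0, :]  # white == dark: no usable signal
        out = compute_reflectance(self.W, W, self.D)
        assert not out.valid[0, 0].any()
        np.testing.assert_array_equal(out.values[0, 0], 0.0)
        assert np.isfinite(out.values).all()

    def test_wavelength_grid_mismatch_lists_both(self):
        with pytest.raises(ValueError, match="grids differ"):
            compute_reflectance(
                self.W, self.W, self.D,
                wavelengths=[500, 600, 700, 800],
                white_wavelengths=[500, 600, 700, 801],
            )


class TestCombine:
    def _cube(self, wavelengths, direction=0):
        wl = np.asarray(wavelengths, dtype=float)
        return ReflectanceCube(
            values=np.tile(wl, (4, 4, 1)), wavelengths=wl, light_direction_id=direction
        )

    def test_full_grids_give_33_bands_477_to_891(self):
        out = combine_vis_vnir(
            self._cube(VIS_WAVELENGTHS_NM), self._cube(VNIR_WAVELENGTHS_NM)
        )
        assert out.values.shape[-1] == 33
        assert out.wavelengths[0] == 477.0 and out.wavelengths[-1] == 891.0
        assert (np.diff(out.wavelengths) > 0).all()

    def test_bands_sorted_even_if_interleaved(self):
        out = combine_vis_vnir(self._cube([500.0, 700.0]), self._cube([600.0, 800.0]))
        np.testing.assert_array_equal(out.wavelengths, [500, 600, 700, 800])
        # values follow their wavelengths through the sort
        np.testing.assert_array_equal(out.values[0, 0], [500, 600, 700, 800])

    def test_overlap_names_collision(self):
        with pytest.raises(ValueError, match="700"):
            combine_vis_vnir(self._cube([600.0, 700.0]), self._cube([700.0, 800.0]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            combine_vis_vnir(self._cube([600.0]), self._cube([]))

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ValueError, match="light direction"):
            combine_vis_vnir(self._cube([500.0]), self._cube([700.0], direction=1))


class TestSpectralTV:
    def test_constant_spectrum_unchanged(self):
        cube = np.full((3, 3, 33), 0.4)
        np.testing.assert_allclose(tv_denoise_spectral(cube, 10.0), cube, atol=1e-8)

    def test_total_variation_decreases_on_noisy_step(self):
        rng = np.random.default_rng(1)
        spec = np.concatenate([np.zeros(16), np.ones(17)]) + rng.normal(0, 0.05, 33)
        cube = np.tile(spec, (2, 2, 1))
        out = tv_denoise_spectral(cube, 10.0)
        tv = lambda v: np.abs(np.diff(v, axis=-1)).sum()
        assert tv(out) < tv(cube)

    def test_large_weight_approaches_input_monotonically(self):
        rng = np.random.default_rng(2)
        cube = np.clip(rng.normal(0.5, 0.1, (2, 2, 33)), 0, 1)
        devs = [
            np.abs(tv_denoise_spectral(cube, w) - cube).max()
            for w in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a > b for a, b in zip(devs, devs[1:]))
        assert devs[-1] < 0.02

    def test_pixels_never_mix(self):
        cube = np.full((2, 2, 33), 0.5)
        cube2 = cube.copy()
        cube2[0, 0] = np.linspace(0, 1, 33)  # only one pixel differs
        a = tv_denoise_spectral(cube, 5.0)
        b = tv_denoise_spectral(cube2, 5.0)
        # untouched pixels agree to solver round-off (iteration counts differ)
        np.testing.assert_allclose(a[1, 1], b[1, 1], atol=1e-12)
        np.testing.assert_allclose(a[0, 1], b[0, 1], atol=1e-12)

    def test_non_finite_rejected(self):
        cube = np.full((2, 2, 33), 0.5)
        cube[0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            tv_denoise_spectral(cube, 1.0)


class TestFeatureStack:
    def setup_method(self):
        self.wl = np.asarray(VIS_WAVELENGTHS_NM + VNIR_WAVELENGTHS_NM, dtype=float)
        rng = np.random.default_rng(3)
        self.albedo = rng.uniform(0.2, 0.8, (40, 40, 33))
        self.depth = rng.normal(0, 3, (40, 40))

    def test_34_channels_normalized_to_unit_interval(self):
        stack = build_feature_stack(self.albedo, {575.0: self.depth}, self.wl)
        assert stack.values.shape == (40, 40, 34)
        assert stack.values.min() >= 0.0 and stack.values.max() <= 1.0
        np.testing.assert_allclose(stack.values.min(axis=(0, 1)), 0.0, atol=1e-6)
        np.testing.assert_allclose(stack.values.max(axis=(0, 1)), 1.0, atol=1e-6)

    def test_nan_pixel_zeroed_others_keep_rank_order(self):
        albedo = self.albedo.copy()
        albedo[5, 5, 10] = np.nan
        stack = build_feature_stack(albedo, {575.0: self.depth}, self.wl)
        clean = build_feature_stack(self.albedo, {575.0: self.depth}, self.wl)
        band = stack.values[:, :, 10]
        assert band[5, 5] <= band.min() + 1e-7
        mask = np.ones((40, 40), dtype=bool)
        mask[5, 5] = False
        a = clean.values[:, :, 10][mask].ravel()
        b = band[mask].ravel()
        np.testing.assert_array_equal(np.argsort(a), np.argsort(b))

    def test_missing_depth_wavelength_lists_available(self):
        with pytest.raises(ValueError, match="575"):
            build_feature_stack(
                self.albedo, {500.0: self.depth}, self.wl, depth_wavelength_nm=575.0
            )

    def test_constant_channel_maps_to_zero(self):
        albedo = self.albedo.copy()
        albedo[:, :, 0] = 0.5
        stack = build_feature_stack(albedo, {575.0: self.depth}, self.wl)
        np.testing.assert_array_equal(stack.values[:, :, 0], 0.0)


def _masks(h=120, w=140, lesion_center=(60, 70), lesion_r=25):
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.hypot(yy - lesion_center[0], xx - lesion_center[1])
    class_mask = np.zeros((h, w), dtype=np.uint8)
    class_mask[d <= lesion_r] = 2
    healthy = d > 1.6 * lesion_r
    return class_mask, healthy


class TestSliceHalfSampling:
    def test_counts_sides_and_margins(self):
        cm, hm = _masks()
        left, right = slice_half_sample(cm, hm, n_lesion=40, n_healthy=20, seed=1)
        assert len(left) == 60 and len(right) == 60
        slice_col = int(round(np.nonzero((cm > 0))[1].mean()))
        for s in left:
            assert s.col < slice_col
        for s in right:
            assert s.col > slice_col
        for s in left + right:
            assert 15 <= s.row < 120 - 15 and 15 <= s.col < 140 - 15
            assert s.label in (0, 2)

    def test_train_test_disjoint(self):
        cm, hm = _masks()
        left, right = slice_half_sample(cm, hm, n_lesion=40, n_healthy=20, seed=2)
        assert not {(s.row, s.col) for s in left} & {(s.row, s.col) for s in right}

    def test_deterministic_per_seed(self):
        cm, hm = _masks()
        a = slice_half_sample(cm, hm, 30, 10, seed=3)
        b = slice_half_sample(cm, hm, 30, 10, seed=3)
        assert a == b

    def test_deficit_reported(self):
        cm, hm = _masks(lesion_r=8)
        with pytest.raises(ValueError, match="deficit"):
            slice_half_sample(cm, hm, n_lesion=500, n_healthy=10, seed=0)

    def test_single_column_lesion_has_no_side_pixels(self):
        # the slice sits on the lesion centroid column; a one-column lesion
        # leaves no lesion pixel strictly on either side
        cm = np.zeros((100, 200), dtype=np.uint8)
        cm[40:60, 50] = 1
        hm = np.ones((100, 200), dtype=bool)
        hm[30:70, 40:60] = False
        with pytest.raises(ValueError, match="lesion pixels"):
            slice_half_sample(cm, hm, n_lesion=20, n_healthy=10, seed=0)


def _stack(h=64, w=64):
    rng = np.random.default_rng(4)
    return FeatureStack(
        values=rng.uniform(0, 1, (h, w, 34)).astype(np.float32),
        wavelengths=np.asarray(VIS_WAVELENGTHS_NM + VNIR_WAVELENGTHS_NM, dtype=float),
    )


class TestWindows:
    def test_pixel_windows_shape_and_center(self):
        from hsskin.preprocess import PixelSample

        stack = _stack()
        pixels = [PixelSample(0, "left", 15, 15, 1), PixelSample(0, "left", 30, 20, 0)]
        out = extract_windows(stack, pixels)
        assert out.cubes.shape == (2, 30, 30, 34)
        # center (15, 15) spans rows/cols 0..29
        np.testing.assert_array_equal(out.cubes[0], stack.values[0:30, 0:30, :])
        # re-reading the window center returns the sampled pixel's features
        np.testing.assert_array_equal(out.cubes[1][15, 15], stack.values[30, 20])
        np.testing.assert_array_equal(out.labels, [1, 0])

    def test_margin_violation_rejected(self):
        from hsskin.preprocess import PixelSample

        with pytest.raises(ValueError, match="margin"):
            extract_windows(_stack(), [PixelSample(0, "left", 10, 30, 0)])

    def test_map_mode_tiling_arithmetic(self):
        out = extract_windows(_stack(64, 64), pixels=None, step=5)
        per_axis = (64 - 30) // 5 + 1
        assert out.grid_shape == (per_axis, per_axis)
        assert len(out) == per_axis**2

    def test_map_mode_boundary_step(self):
        out = extract_windows(_stack(64, 64), pixels=None, step=34)
        assert out.grid_shape == (2, 2)
        out1 = extract_windows(_stack(64, 64), pixels=None, step=40)
        assert out1.grid_shape == (1, 1)

    def test_stack_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            extract_windows(_stack(20, 64), pixels=None)


def _subcubes(counts, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(n, cls) for cls, n in counts.items()])
    n = labels.size
    return SubCubeSet(
        cubes=rng.uniform(size=(n, 4, 4, 3)).astype(np.float32),
        labels=labels,
        scene_ids=np.zeros(n, dtype=np.int64),
        provenance=np.full(n, PROV_ORIGINAL, dtype=np.int8),
    )


class TestBalanceAndAugment:
    def test_oversample_to_majority(self):
        out = balance_oversample(_subcubes({0: 25, 1: 17, 2: 16}), seed=0)
        assert out.class_counts() == {0: 25, 1: 25, 2: 25}
        added = out.provenance == PROV_OVERSAMPLED
        assert added.sum() == (25 - 17) + (25 - 16)

    def test_balanced_set_is_fixed_point(self):
        s = _subcubes({0: 10, 1: 10, 2: 10})
        assert balance_oversample(s, seed=0) is s

    def test_oversample_deterministic(self):
        a = balance_oversample(_subcubes({0: 20, 1: 5, 2: 9}), seed=7)
        b = balance_oversample(_subcubes({0: 20, 1: 5, 2: 9}), seed=7)
        np.testing.assert_array_equal(a.cubes, b.cubes)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            balance_oversample(_subcubes({0: 10, 1: 10}), seed=0)

    @pytest.mark.parametrize("n", [1, 13, 100])
    def test_flips_exactly_quadruple(self, n):
        s = _subcubes({0: n})
        out = augment_flips(s)
        assert len(out) == 4 * n
        np.testing.assert_array_equal(out.labels, np.tile(s.labels, 4))

    def test_flip_is_involution(self):
        s = _subcubes({0: 3, 1: 3, 2: 3}, seed=1)
        out = augment_flips(s)
        n = len(s)
        # flipping the vertical flip restores the original
        np.testing.assert_array_equal(out.cubes[n : 2 * n][:, ::-1], s.cubes)
        np.testing.assert_array_equal(out.cubes[2 * n : 3 * n][:, :, ::-1], s.cubes)
        np.testing.assert_array_equal(
            out.cubes[3 * n :][:, ::-1, ::-1], s.cubes
        )
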