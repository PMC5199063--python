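"""Feature families against analytic and brute-force oracles."""

import numpy as np
import pytest
import pywt
from scipy import ndimage

from qifagree import (
    ImageVolume,
    PhantomSpec,
    SegmentationMask,
    TextureParams,
    default_registry,
    extract_all,
    generate_phantom,
)
from qifagree.qif import (
    GLCM_NAMES,
    LAWS_NAMES,
    extract_glcm,
    extract_histogram_stats,
    extract_laws,
    extract_log,
    extract_shape_index,
    extract_sigmoid_slope,
    extract_size_shape,
    extract_wavelet,
    fit_sigmoid,
    glcm_matrix,
    laws_response,
    log_response,
    shape_index_values,
    unique_directions_3d,
    wavelet_subbands,
)
from qifagree.qif.laws import LAWS_VECTORS
from qifagree.qif.registry import FeatureExtractionError

from conftest import cube_mask


def uniform_volume_for(mask: SegmentationMask, inside=50.0, outside=-800.0) -> ImageVolume:
    data = np.full(mask.shape, outside)
    data[mask.data] = inside
    return ImageVolume(data, mask.spacing)


class TestSizeShape:
    def test_ball_volume_within_2pct_and_low_eccentricity(self, ball_volume_mask):
        vol, mask = ball_volume_mask
        feats = extract_size_shape(vol, mask)
        assert feats["Volume"] == pytest.approx(4 / 3 * np.pi * 125, rel=0.02)
        assert feats["Eccentricity"] < 0.05
        assert feats["Elongation"] == pytest.approx(1.0, abs=0.05)

    def test_ball_more_compact_than_elongated_ellipsoid(self, ball_volume_mask):
        vol, mask = ball_volume_mask
        ball_c = extract_size_shape(vol, mask)["Compactness"]
        # 2:1 ellipsoid of equal volume: semi-axes (2a, a, a) with a = 5/2^(1/3)
        a = 5.0 / 2 ** (1 / 3)
        spec = PhantomSpec(
            semi_axes_mm=(2 * a, a, a),
            lobulation_amplitude=0,
            texture_amplitude_hu=0,
            noise_sd_hu=0,
        )
        evol, emask = generate_phantom(spec, spacing_mm=0.5)
        ell = extract_size_shape(evol, emask)
        assert ell["Volume"] == pytest.approx(4 / 3 * np.pi * 125, rel=0.03)
        assert ball_c > ell["Compactness"]
        assert ball_c <= 1.0 + 1e-6

    def test_cube_space_diagonal(self):
        mask = cube_mask(20, spacing=0.5)  # 10 mm cube
        vol = uniform_volume_for(mask)
        feats = extract_size_shape(vol, mask)
        # surface-voxel centers span 9.5 mm per edge -> diagonal of centers
        assert feats["Max_Diameter_3D"] == pytest.approx(10 * np.sqrt(3), abs=0.5 * np.sqrt(3))

    def test_invariant_to_hu_shift_and_axis_permutation(self, ball_volume_mask):
        vol, mask = ball_volume_mask
        base = extract_size_shape(vol, mask)
        shifted = ImageVolume(vol.data + 100.0, vol.spacing)
        assert extract_size_shape(shifted, mask) == base
        permuted_mask = SegmentationMask(
            np.transpose(mask.data, (2, 0, 1)), mask.spacing
        )
        permuted_vol = ImageVolume(np.transpose(vol.data, (2, 0, 1)), vol.spacing)
        permuted = extract_size_shape(permuted_vol, permuted_mask)
        for key in ("Volume", "Surface_Area", "Compactness", "Eccentricity"):
            assert permuted[key] == pytest.approx(base[key], rel=1e-9)


class TestHistogram:
    def grid(self, values):
        arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
        data = np.tile(arr, (3, 3, 1))
        mask = SegmentationMask(np.ones_like(data, dtype=bool), (0.5, 0.5, 0.5))
        return ImageVolume(data, (0.5, 0.5, 0.5)), mask

    def test_constant_region_degenerate_conventions(self):
        vol, mask = self.grid([5.0, 5.0, 5.0, 5.0])
        f = extract_histogram_stats(vol, mask)
        assert f["SD"] == 0.0
        assert f["Histogram_Entropy"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Kurtosis"] == 0.0

    def test_hand_computed_moments(self):
        vol, mask = self.grid([0.0, 0.0, 10.0, 10.0])
        f = extract_histogram_stats(vol, mask)
        assert f["Mean"] == pytest.approx(5.0)
        assert f["SD"] == pytest.approx(5.0)  # population SD
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_mirroring_negates_skewness_keeps_sd(self):
        rng = np.random.default_rng(8)
        values = rng.gamma(2.0, 10.0, size=64)
        vol, mask = self.grid(values)
        f = extract_histogram_stats(vol, mask)
        mirrored, mask2 = self.grid(2 * values.mean() - values)
        g = extract_histogram_stats(mirrored, mask2)
        assert g["Skewness"] == pytest.approx(-f["Skewness"], rel=1e-9)
        assert g["SD"] == pytest.approx(f["SD"], rel=1e-9)


class TestGLCM:
    def test_constant_region_single_cell_matrix(self):
        mask = cube_mask(6)
        vol = uniform_volume_for(mask, inside=30.0)
        f = extract_glcm(vol, mask)
        assert f["GLCM_Energy"] == pytest.approx(1.0)
        assert f["GLCM_Contrast"] == pytest.approx(0.0)
        assert f["GLCM_Entropy"] == pytest.approx(0.0)

    def test_checkerboard_counts_match_brute_force_oracle(self):
        # 4x4x1 two-level in-plane checkerboard, in-plane offsets only
        board = np.indices((1, 4, 4)).sum(axis=0) % 2 * 100.0
        vol = ImageVolume(board.astype(float), (0.5, 0.5, 0.5))
        mask = SegmentationMask(np.ones_like(board, dtype=bool), (0.5, 0.5, 0.5))
        dirs = [(0, 1, 0), (0, 0, 1), (0, 1, 1), (0, 1, -1)]
        params = TextureParams(bin_width_hu=100.0)
        p = glcm_matrix(vol, mask, params, directions=dirs)

        # brute-force pair enumeration over all voxel pairs at those offsets
        levels = (board / 100).astype(int)
        counts = np.zeros((2, 2))
        for dz, dy, dx in dirs:
            for z in range(1):
                for y in range(4):
                    for x in range(4):
                        y2, x2 = y + dy, x + dx
                        if 0 <= y2 < 4 and 0 <= x2 < 4:
                            a, b = levels[z, y, x], levels[z, y2, x2]
                            counts[a, b] += 1
                            counts[b, a] += 1
        np.testing.assert_allclose(p, counts / counts.sum(), atol=1e-12)

    def test_matrix_symmetric_probability_distribution(self, textured_lesion):
        vol, mask = textured_lesion
        p = glcm_matrix(vol, mask)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p, p.T, atol=1e-15)

    def test_thirteen_unique_directions(self):
        dirs = unique_directions_3d()
        assert len(dirs) == 13
        assert len({d for d in dirs} | {tuple(-c for c in d) for d in dirs}) == 26


class TestLaws:
    def test_zero_sum_kernels_annihilate_constants(self):
        mask = cube_mask(10)
        vol = uniform_volume_for(mask, inside=75.0, outside=75.0)
        f = extract_laws(vol, mask)
        for name in LAWS_NAMES:
            assert f[name] == pytest.approx(0.0, abs=1e-9)

    def test_ramp_response_matches_dot_product_oracle(self):
        # intensity = x index; E5 along x: response = E5 . (offsets) * sum(L5)^2
        shape = (12, 12, 12)
        data = np.broadcast_to(np.arange(12, dtype=float), shape).copy()
        resp = laws_response(data, ("L", "L", "E"))  # E on x axis
        e5, l5 = LAWS_VECTORS["E"], LAWS_VECTORS["L"]
        expected = float(np.dot(e5, np.arange(-2, 3))) * l5.sum() ** 2
        interior = resp[4:8, 4:8, 4:8]
        np.testing.assert_allclose(interior, expected, rtol=1e-12)

    def test_separable_equals_direct_3d_convolution(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(14, 14, 14))
        for triple in (("E", "L", "L"), ("S", "R", "L"), ("W", "W", "W")):
            kern = np.einsum(
                "i,j,k->ijk",
                LAWS_VECTORS[triple[0]],
                LAWS_VECTORS[triple[1]],
                LAWS_VECTORS[triple[2]],
            )
            direct = ndimage.correlate(data, kern, mode="nearest")
            sep = laws_response(data, triple)
            np.testing.assert_allclose(sep, direct, rtol=1e-6, atol=1e-8)

    def test_energy_invariant_under_global_offset(self, textured_lesion):
        vol, mask = textured_lesion
        f1 = extract_laws(vol, mask)
        f2 = extract_laws(ImageVolume(vol.data + 500.0, vol.spacing), mask)
        for name in LAWS_NAMES:
            assert f2[name] == pytest.approx(f1[name], rel=1e-9, abs=1e-9)


class TestLoG:
    def test_constant_volume_zero_response(self):
        mask = cube_mask(8)
        vol = uniform_volume_for(mask, inside=10.0, outside=10.0)
        f = extract_log(vol, mask)
        assert f["LoG_SD_s2.5"] == 0.0
        assert f["LoG_Mean_s2.5"] == pytest.approx(0.0, abs=1e-9)

    def test_affine_field_has_zero_laplacian_interior(self):
        zz, yy, xx = np.meshgrid(*[np.arange(24) * 0.5] * 3, indexing="ij")
        vol = ImageVolume(3.0 * zz - 2.0 * yy + 0.7 * xx + 5.0, (0.5, 0.5, 0.5))
        resp = log_response(vol, sigma_mm=1.0)
        interior = resp[8:-8, 8:-8, 8:-8]
        np.testing.assert_allclose(interior, 0.0, atol=1e-6)

    def test_gaussian_blob_center_matches_analytic(self):
        # LoG_sigma_f of a Gaussian blob sigma_b = Laplacian of Gaussian with
        # sigma_t^2 = sigma_f^2 + sigma_b^2; at the center: -3 A' / sigma_t^2
        spacing = 0.5
        n = 49  # odd: the center voxel coincides with the blob center
        c = (n - 1) / 2 * spacing
        zz, yy, xx = np.meshgrid(*[np.arange(n) * spacing] * 3, indexing="ij")
        sig_b = 2.0
        A = 100.0
        r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
        vol = ImageVolume(A * np.exp(-r2 / (2 * sig_b**2)), (spacing,) * 3)
        sig_f = 1.5
        resp = log_response(vol, sigma_mm=sig_f)
        sig_t2 = sig_b**2 + sig_f**2
        A_t = A * (sig_b**2 / sig_t2) ** 1.5
        expected = -3.0 * A_t / sig_t2
        center = resp[n // 2, n // 2, n // 2]
        assert center == pytest.approx(expected, rel=0.02)
        assert center < 0


class TestWavelet:
    def test_constant_volume_zero_detail_energy(self):
        mask = cube_mask(12)
        vol = uniform_volume_for(mask, inside=44.0, outside=44.0)
        f = extract_wavelet(vol, mask)
        for k, v in f.items():
            if k.endswith("_Energy"):
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_transform_preserves_energy(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(16, 16, 16))
        vol = ImageVolume(data, (0.5, 0.5, 0.5))
        params = TextureParams()
        coeffs = pywt.wavedecn(data, params.wavelet, mode="periodization", level=2)
        total = np.sum(coeffs[0] ** 2)
        for level in coeffs[1:]:
            for arr in level.values():
                total += np.sum(arr**2)
        assert total == pytest.approx(np.sum(data**2), rel=1e-9)

    def test_separable_product_signal_factorizes(self):
        # the ddd subband of an outer-product volume is the outer product of
        # the 1D detail coefficients -- checks axis conventions end to end
        rng = np.random.default_rng(6)
        u, v, w = rng.normal(size=(3, 8))
        data = np.einsum("i,j,k->ijk", u, v, w)
        vol = ImageVolume(data, (0.5, 0.5, 0.5))
        params = TextureParams(wavelet_levels=1)
        level1 = wavelet_subbands(vol, params)[0]
        _, du = pywt.dwt(u, params.wavelet, mode="periodization")
        _, dv = pywt.dwt(v, params.wavelet, mode="periodization")
        _, dw = pywt.dwt(w, params.wavelet, mode="periodization")
        expected = np.einsum("i,j,k->ijk", du, dv, dw)
        np.testing.assert_allclose(level1["ddd"], expected, rtol=1e-9, atol=1e-12)

    def test_too_small_volume_rejected(self):
        mask = cube_mask(1, pad=0, spacing=0.5)
        vol = uniform_volume_for(mask)
        with pytest.raises(ValueError, match="small"):
            extract_wavelet(vol, mask)


class TestShapeIndex:
    def test_ball_mass_in_cap_bin(self, ball_volume_mask):
        vol, mask = ball_volume_mask
        f = extract_shape_index(vol, mask)
        hist = [f[f"Shape_Index_{i}"] for i in range(1, 10)]
        assert hist[-1] == max(hist)
        assert hist[-1] > 0.5

    def test_histogram_sums_to_one(self, textured_lesion):
        vol, mask = textured_lesion
        f = extract_shape_index(vol, mask)
        assert sum(f[f"Shape_Index_{i}"] for i in range(1, 10)) == pytest.approx(1.0)

    def test_cylinder_dominated_by_ridge_values(self):
        # long solid cylinder: kappa_1 = 1/r, kappa_2 ~ 0 -> SI ~ +0.5
        n, r_mm, spacing = 64, 4.0, 0.5
        zz = np.arange(n)
        yy, xx = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
        c = 11.5 * spacing
        circle = ((yy * spacing - c) ** 2 + (xx * spacing - c) ** 2) <= r_mm**2
        arr = np.broadcast_to(circle, (n, 24, 24)).copy()
        mask = SegmentationMask(arr, (spacing,) * 3)
        si = shape_index_values(mask)
        # exclude end caps: central 80% of samples by position is not tracked,
        # so instead require the median SI to sit near the ridge value
        assert np.median(si) == pytest.approx(0.5, abs=0.15)


class TestSigmoid:
    def test_printed_profile_matches_grid_search_oracle(self):
        t = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        s = np.array([0.0, 4.7, 50.0, 95.3, 100.0])
        A, B, t0, w = fit_sigmoid(t, s)
        assert B == pytest.approx(100.0, rel=0.05)
        assert w == pytest.approx(1 / 3, rel=0.05)
        slope = abs(B) / (4 * w)
        assert slope == pytest.approx(75.0, rel=0.05)

        # dense grid-search oracle over (A, B, t0, w)
        best = (np.inf, None)
        for Ag in np.linspace(-5, 5, 11):
            for Bg in np.linspace(80, 120, 41):
                for t0g in np.linspace(-0.5, 0.5, 11):
                    for wg in np.linspace(0.2, 0.6, 41):
                        pred = Ag + Bg / (1 + np.exp(-(t - t0g) / wg))
                        sse = float(np.sum((pred - s) ** 2))
                        if sse < best[0]:
                            best = (sse, (Ag, Bg, t0g, wg))
        _, (Ag, Bg, t0g, wg) = best
        assert abs(Bg) / (4 * wg) == pytest.approx(slope, rel=0.05)

    def test_sharper_edge_gives_larger_slope(self):
        t = np.arange(-4, 4.01, 0.25)
        for w_true, w_other in [(0.3, 1.0)]:
            sa = 100 / (1 + np.exp(-t / w_true))
            sb = 100 / (1 + np.exp(-t / w_other))
            _, Ba, _, wa = fit_sigmoid(t, sa)
            _, Bb, _, wb = fit_sigmoid(t, sb)
            assert abs(Ba) / (4 * wa) > abs(Bb) / (4 * wb)

    def test_contrast_free_profiles_flagged_not_fit(self):
        mask = cube_mask(8)
        vol = uniform_volume_for(mask, inside=0.0, outside=0.0)
        with pytest.raises(ValueError, match="failed"):
            extract_sigmoid_slope(vol, mask)

    def test_lesion_slope_tracks_simulated_blur(self, ball_volume_mask):
        vol, mask = ball_volume_mask
        sharp = extract_sigmoid_slope(vol, mask)["Sigmoid_Slope"]
        blurred = ImageVolume(ndimage.gaussian_filter(vol.data, 2.0), vol.spacing)
        soft = extract_sigmoid_slope(blurred, mask)["Sigmoid_Slope"]
        assert sharp > soft


class TestExtractAll:
    def test_default_registry_has_89_unique_names(self):
        reg = default_registry()
        assert len(reg) == 89
        assert len(set(reg.names)) == 89

    def test_returns_one_finite_value_per_registry_entry(self, textured_lesion):
        vol, mask = textured_lesion
        values = extract_all(vol, mask)
        reg = default_registry()
        assert list(values) == reg.names
        assert all(np.isfinite(v) for v in values.values())

    def test_deterministic_on_same_input(self, textured_lesion):
        vol, mask = textured_lesion
        assert extract_all(vol, mask) == extract_all(vol, mask)

    def test_hu_offset_moves_mean_not_shape(self, textured_lesion):
        vol, mask = textured_lesion
        base = extract_all(vol, mask)
        shifted = extract_all(ImageVolume(vol.data + 100.0, vol.spacing), mask)
        assert shifted["Mean"] == pytest.approx(base["Mean"] + 100.0, rel=1e-9)
        for name in ("Volume", "Compactness", "Eccentricity", "Max_Diameter_3D"):
            assert shifted[name] == pytest.approx(base[name], rel=1e-12)

    def test_non_isotropic_volume_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), (1.0, 0.5, 0.5))
        mask = SegmentationMask(np.ones((8, 8, 8), dtype=bool), (1.0, 0.5, 0.5))
        with pytest.raises(FeatureExtractionError, match="isotropic"):
            extract_all(vol, mask)

    def test_registry_manifest_roundtrip(self, tmp_path):
        from qifagree.qif.registry import FeatureRegistry

        reg = default_registry()
        path = tmp_path / "manifest.csv"
        reg.to_manifest(path)
        back = FeatureRegistry.from_manifest(path)
        assert back.names == reg.names
        assert [d.family for d in back.descriptors] == [d.family for d in reg.descriptors]
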