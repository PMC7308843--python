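"""Color moments, GLGCM and Gabor textures, and feature fusion."""

import math

import numpy as np
import pytest

from _oracles import glgcm_oracle
from berryspec.errors import AlignmentError
from berryspec.features import (
    GLGCMConfig,
    assemble_features,
    build_gabor_kernel,
    color_moments,
    gabor_features,
    glgcm_features,
    glgcm_joint_histogram,
    texture_block,
)
from berryspec.hsi_io import Hypercube, Mask
from berryspec.preprocessing import SpectraTable

FULL8 = Mask(np.ones((8, 8), bool))


def _cube_from_channels(r, g, b, extra_bands=0):
    """Cube with R/G/B channel images at 700/500/400 nm."""
    planes = [np.asarray(b, float), np.asarray(g, float), np.asarray(r, float)]
    wl = [400.0, 500.0, 700.0]
    for k in range(extra_bands):
        planes.append(np.zeros_like(planes[0]))
        wl.append(710.0 + k)
    return Hypercube(np.stack(planes, axis=2), np.array(wl), "reflectance")


class TestColorMoments:
    def test_constant_channels_have_zero_spread_and_skew(self):
        c = _cube_from_channels(
            np.full((4, 4), 0.6), np.full((4, 4), 0.3), np.full((4, 4), 0.1)
        )
        out = color_moments(c, Mask(np.ones((4, 4), bool)), (700.0, 500.0, 400.0))
        assert out.shape == (9,)
        assert np.allclose(out, [0.6, 0, 0, 0.3, 0, 0, 0.1, 0, 0], atol=1e-12)

    def test_symmetric_two_pixel_distribution(self):
        img = np.zeros((1, 2))
        img[0, 1] = 2.0
        c = _cube_from_channels(img, img, img)
        out = color_moments(c, Mask(np.ones((1, 2), bool)), (700.0, 500.0, 400.0))
        assert np.allclose(out[:3], [1.0, 1.0, 0.0], atol=1e-12)

    def test_background_pixels_never_influence_features(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(6, 6))
        mask = Mask(np.pad(np.ones((4, 4), bool), 1))
        c1 = _cube_from_channels(img, img, img)
        img2 = img.copy()
        img2[~mask.values] = 99.0
        c2 = _cube_from_channels(img2, img2, img2)
        a = color_moments(c1, mask, (700.0, 500.0, 400.0))
        b = color_moments(c2, mask, (700.0, 500.0, 400.0))
        assert np.array_equal(a, b)

    def test_empty_mask_rejected(self):
        c = _cube_from_channels(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            color_moments(c, Mask(np.zeros((2, 2), bool)), (700.0, 500.0, 400.0))


class TestGLGCM:
    def test_constant_image_degenerates_to_single_cell(self):
        f = glgcm_features(np.full((8, 8), 3.0), FULL8)
        assert f.shape == (15,)
        assert f[4] == 1.0            # energy
        assert f[10] == f[11] == f[12] == 0.0  # entropies
        assert f[0] == 1.0            # all mass at grad level 0
        assert f[9] == 0.0            # correlation defined as 0

    def test_checkerboard_matches_brute_force_oracle(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 * 0.8 + 0.1
        ours = glgcm_features(img, Mask(np.ones((4, 4), bool)))
        assert np.allclose(ours, glgcm_oracle(img), atol=1e-12)

    def test_random_images_match_brute_force_oracle(self):
        for seed in range(200):
            img = np.random.default_rng(seed).uniform(size=(8, 8))
            assert np.allclose(
                glgcm_features(img, FULL8), glgcm_oracle(img), atol=1e-10
            ), f"seed {seed}"

    def test_probability_table_and_bounded_statistics(self):
        for seed in range(20):
            img = np.random.default_rng(seed).uniform(size=(8, 8))
            p = glgcm_joint_histogram(img, FULL8)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            f = glgcm_features(img, FULL8)
            assert 0 < f[4] <= 1.0       # energy
            assert f[10] >= 0 and f[11] >= 0 and f[12] >= 0
            assert 0 < f[14] <= 1.0      # homogeneity

    def test_background_fill_keeps_features_mask_local(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(10, 10))
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        tampered = img.copy()
        tampered[~mask] = 42.0
        a = glgcm_features(img, Mask(mask))
        b = glgcm_features(tampered, Mask(mask))
        assert np.array_equal(a, b)

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            glgcm_features(np.ones((8, 8)), Mask(np.pad(np.ones((2, 2), bool), 3)))

    def test_level_config_validated(self):
        with pytest.raises(ValueError):
            GLGCMConfig(gray_levels=1)


class TestGabor:
    def test_constant_image_gives_null_response(self):
        out = gabor_features(np.full((40, 40), 2.0), Mask(np.ones((40, 40), bool)))
        assert out.shape == (3,)
        assert abs(out[0]) <= 1e-8 and abs(out[1]) <= 1e-8 and out[2] == 0.0

    def test_kernel_has_zero_dc_gain(self):
        k = build_gabor_kernel()
        assert abs(k.sum()) <= 1e-12

    def test_orientation_selectivity_at_60_degrees(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = Mask(np.ones((64, 64), bool))

        def grating(theta_deg):
            t = math.radians(theta_deg)
            return np.cos(2 * np.pi * 0.25 * (xx * math.cos(t) + yy * math.sin(t)))

        aligned = gabor_features(grating(60.0), mask)
        orthogonal = gabor_features(grating(150.0), mask)
        assert aligned[0] > orthogonal[0]

    def test_convolution_agrees_with_direct_sum_in_the_interior(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(41, 41))
        k = build_gabor_kernel()
        kh, kw = k.shape
        r, c = 20, 20
        patch = img[r - kh // 2 : r + kh // 2 + 1, c - kw // 2 : c + kw // 2 + 1]
        # ndimage.convolve flips the kernel; reproduce by direct summation
        direct = (patch * k[::-1, ::-1]).sum()
        from scipy import ndimage

        real = ndimage.convolve(img, np.real(k), mode="nearest")[r, c]
        imag = ndimage.convolve(img, np.imag(k), mode="nearest")[r, c]
        assert complex(real, imag) == pytest.approx(complex(direct), abs=1e-10)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            gabor_features(np.ones((5, 5)), Mask(np.ones((5, 5), bool)))


class TestTextureBlock:
    def _cube(self, img1, img2):
        return Hypercube(
            np.stack([img1, img2], axis=2), np.array([676.0, 910.0]), "reflectance"
        )

    def test_length_and_symmetry_for_identical_bands(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(40, 40))
        mask = Mask(np.ones((40, 40), bool))
        out = texture_block(self._cube(img, img), mask, (676.0, 910.0))
        assert out.shape == (36,)
        assert np.array_equal(out[:18], out[18:])

    def test_band_pair_resolves_to_nearest_grid_bands(self):
        from berryspec.hsi_io import nearest_band
        from berryspec.synthetic import default_wavelengths

        wl = default_wavelengths()
        assert abs(wl[nearest_band(wl, 676.0)] - 676.0) <= 2.31 / 2
        assert abs(wl[nearest_band(wl, 910.0)] - 910.0) <= 2.31 / 2


class TestAssembleFeatures:
    def _spectra(self, n=4, bands=260):
        rng = np.random.default_rng(4)
        wl = np.linspace(400, 1000, bands)
        return SpectraTable(rng.uniform(size=(n, bands)), wl, [f"s{i}" for i in range(n)])

    def test_spectral_only_equals_input_columns(self):
        sp = self._spectra()
        out = assemble_features(sp, include={"spectral"})
        assert np.array_equal(out.F, sp.X)
        assert set(out.blocks) == {"spectral"}

    def test_fused_column_counts(self):
        sp = self._spectra()
        color = np.zeros((4, 9))
        texture = np.zeros((4, 36))
        both = assemble_features(sp, color=color, include=("spectral", "color"))
        assert both.F.shape[1] == 269
        full = assemble_features(
            sp, color=color, texture=texture,
            include=("spectral", "color", "texture"),
        )
        assert full.F.shape[1] == 305
        assert full.blocks.count("color") == 9
        assert full.blocks.count("texture") == 36

    def test_id_mismatch_rejected(self):
        from berryspec.features import FeatureTable

        sp = self._spectra()
        wrong = FeatureTable(np.zeros((4, 9)), [f"c{i}" for i in range(9)],
                             ["color"] * 9, ["x0", "x1", "x2", "x3"])
        with pytest.raises(AlignmentError):
            assemble_features(sp, color=wrong, include=("spectral", "color"))

    def test_row_count_mismatch_rejected(self):
        sp = self._spectra()
        with pytest.raises(AlignmentError):
            assemble_features(sp, color=np.zeros((3, 9)), include=("spectral", "color"))
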