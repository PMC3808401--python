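"""The 48-element feature extractor: palette, color ratio, entropy,
edge count and line counts, with brute-force oracles and invariances."""

import numpy as np
import pytest

from finstripe import (FEATURE_NAMES, ClassSpec, MaskedImage, color_ratio,
                       entropy, extract_features, generate_fish_image,
                       line_features, quantize_palette)
from finstripe.errors import DegeneratePaletteError, EmptyForegroundError
from finstripe.features import (COLOR_FEATURE_NAMES, edge_map,
                                edge_pixel_count, gray_histogram, to_grayscale)
from finstripe.preprocess import SENTINEL

from conftest import BLUE, BROWN, make_block_image


def brute_force_entropy(image):
    """Per-pixel tally oracle, independent of the histogram code path."""
    gray = to_grayscale(image)
    tally = {}
    h, w = gray.shape
    n = 0
    for r in range(h):
        for c in range(w):
            if image.mask[r, c]:
                tally[int(gray[r, c])] = tally.get(int(gray[r, c]), 0) + 1
                n += 1
    total = 0.0
    for count in tally.values():
        p = count / n
        total -= p * np.log2(p)
    return total


class TestPalette:
    def test_three_distinct_colors_exact_counts_and_padding(self):
        img = make_block_image([(BROWN, 300), (BLUE, 200), ((10, 200, 10), 100)])
        pal = quantize_palette(img, seed=0)
        assert pal.counts == [300, 200, 100, 0, 0, 0, 0]
        assert pal.entries[0].rgb == tuple(float(c) for c in BROWN)
        assert pal.entries[1].rgb == tuple(float(c) for c in BLUE)
        # padding repeats the last real color at count zero
        assert pal.entries[3].rgb == pal.entries[2].rgb

    def test_single_color_foreground(self):
        img = make_block_image([(BROWN, 123)])
        pal = quantize_palette(img, seed=0)
        assert pal.counts[0] == 123
        assert pal.entries[0].rgb == tuple(float(c) for c in BROWN)

    def test_position_invariance_under_pixel_shuffle(self):
        rng = np.random.default_rng(4)
        pixels = rng.integers(0, 250, size=(40, 40, 3)).astype(np.uint8)
        img = MaskedImage.from_raster(pixels)
        flat = pixels.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(pixels.shape)
        img2 = MaskedImage.from_raster(shuffled)
        p1 = quantize_palette(img, seed=9)
        p2 = quantize_palette(img2, seed=9)
        assert p1.counts == p2.counts
        for a, b in zip(p1.entries, p2.entries):
            np.testing.assert_allclose(a.rgb, b.rgb)

    def test_counts_conserve_foreground_size(self, striped_image):
        noisy_spec = ClassSpec(label="n", palette=[(BROWN, 0.7), (BLUE, 0.3)],
                               stripe_count=2, body_width_px=200,
                               body_height_px=60, color_noise_sd=10.0)
        img = generate_fish_image(noisy_spec, seed=5)
        pal = quantize_palette(img, seed=0)
        assert sum(pal.counts) == img.n_foreground

    def test_hsv_matches_rgb_entry(self):
        import colorsys
        img = make_block_image([(BROWN, 300), (BLUE, 200)])
        pal = quantize_palette(img, seed=0)
        for e in pal.entries:
            expected = colorsys.rgb_to_hsv(*(c / 255.0 for c in e.rgb))
            np.testing.assert_allclose(e.hsv, expected)

    def test_empty_foreground_rejected(self):
        pixels = np.empty((5, 5, 3), dtype=np.uint8)
        pixels[:] = SENTINEL
        with pytest.raises(EmptyForegroundError):
            quantize_palette(MaskedImage.from_raster(pixels), seed=0)


class TestColorRatio:
    def test_600_over_500_pixels_gives_1_2(self):
        img = make_block_image([(BROWN, 600), (BLUE, 500)])
        assert color_ratio(quantize_palette(img, seed=0)) == pytest.approx(1.2)

    def test_equal_counts_give_unity(self):
        img = make_block_image([(BROWN, 250), (BLUE, 250)])
        assert color_ratio(quantize_palette(img, seed=0)) == 1.0

    def test_single_color_is_degenerate(self):
        img = make_block_image([(BROWN, 100)])
        with pytest.raises(DegeneratePaletteError, match="degenerate"):
            color_ratio(quantize_palette(img, seed=0))


class TestEntropy:
    def test_constant_intensity_gives_zero(self):
        img = make_block_image([((100, 100, 100), 400)])
        assert entropy(img) == 0.0

    def test_fair_split_gives_one_bit(self):
        img = make_block_image([((0, 0, 0), 200), ((255, 255, 255), 200)])
        assert entropy(img) == pytest.approx(1.0)

    def test_half_quarter_eighth_histogram_gives_1_75_bits(self):
        img = make_block_image([((0, 0, 0), 400), ((255, 255, 255), 200),
                                ((100, 100, 100), 100), ((200, 200, 200), 100)])
        assert entropy(img) == pytest.approx(1.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(8, 33))
        pixels = rng.integers(0, 256, size=(size, size, 3)).astype(np.uint8)
        img = MaskedImage.from_raster(pixels)
        assert entropy(img) == pytest.approx(brute_force_entropy(img))

    def test_bounds_zero_to_eight_bits(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pixels = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
            img = MaskedImage.from_raster(pixels)
            assert 0.0 <= entropy(img) <= 8.0

    def test_histogram_sums_to_one(self, striped_image):
        p = gray_histogram(striped_image)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (p >= 0).all()


class TestEdgeCount:
    def test_constant_foreground_has_no_edges(self):
        img = make_block_image([((100, 100, 100), 900)], width=30)
        assert edge_pixel_count(img) == 0.0

    def test_normalization_matches_direct_edge_map_count(self):
        pixels = np.empty((40, 40, 3), dtype=np.uint8)
        pixels[:] = SENTINEL
        pixels[4:36, 4:20] = (0, 0, 0)
        pixels[4:36, 20:36] = (255, 255, 255)
        img = MaskedImage.from_raster(pixels)
        n_edges = int(edge_map(img).sum())
        assert n_edges > 0
        assert edge_pixel_count(img) == pytest.approx(n_edges / img.n_foreground)

    def test_upscaling_decreases_normalized_count(self):
        pixels = np.empty((40, 40, 3), dtype=np.uint8)
        pixels[:] = SENTINEL
        pixels[4:36, 4:20] = (0, 0, 0)
        pixels[4:36, 20:36] = (255, 255, 255)
        small = MaskedImage.from_raster(pixels)
        big = MaskedImage.from_raster(np.kron(pixels, np.ones((2, 2, 1))
                                              ).astype(np.uint8))
        assert edge_pixel_count(big) < edge_pixel_count(small)


class TestLineFeatures:
    def test_constant_image_has_no_lines(self):
        img = make_block_image([((100, 100, 100), 900)], width=30)
        assert line_features(img, seed=0) == (0, 0, 0)

    def test_three_vertical_bars_give_six_vertical_lines(self, striped_image):
        n_h, n_d, n_v = line_features(striped_image, seed=0)
        assert n_v >= 6
        assert n_d == 0

    def test_rotating_raster_swaps_horizontal_and_vertical(self, striped_image):
        n_h, n_d, n_v = line_features(striped_image, seed=0)
        rot = MaskedImage(pixels=np.rot90(striped_image.pixels).copy(),
                          mask=np.rot90(striped_image.mask).copy())
        r_h, r_d, r_v = line_features(rot, seed=0)
        assert r_h >= 6 and r_v <= n_h + 1
        assert r_d == n_d


class TestExtractFeatures:
    def test_vector_has_48_named_features(self, striped_image):
        fv = extract_features(striped_image, seed=0)
        assert len(fv) == 48
        assert fv.names == FEATURE_NAMES

    def test_color_block_has_42_features(self):
        assert len(COLOR_FEATURE_NAMES) == 42
        assert COLOR_FEATURE_NAMES[0] == "Color_0_r"
        assert COLOR_FEATURE_NAMES[-1] == "Color_6_v"

    def test_background_pixels_never_affect_features(self, striped_image):
        altered = striped_image.pixels.copy()
        altered[~striped_image.mask] = (90, 90, 90)
        # same foreground, different background, mask supplied explicitly
        img2 = MaskedImage(pixels=altered, mask=striped_image.mask.copy())
        fv1 = extract_features(striped_image, seed=3)
        fv2 = extract_features(img2, seed=3)
        np.testing.assert_allclose(fv1.values, fv2.values)

    def test_degenerate_ratio_recorded_as_nan(self):
        img = make_block_image([((100, 100, 100), 400)])
        fv = extract_features(img, seed=0)
        assert np.isnan(fv["Color_ratio"])
        assert np.isfinite(fv["Entropy"])
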