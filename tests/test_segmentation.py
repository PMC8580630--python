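"""Tests for color conversion, Otsu thresholding, morphology, segmentation."""

import numpy as np
import pytest

from dermelm.exceptions import ConfigError, DataError
from dermelm.preprocessing import denoise
from dermelm.segmentation import (
    SegmentationConfig,
    morphology,
    normalize_channels,
    otsu_threshold,
    rgb_to_xyz,
    segment,
    structuring_element,
)
from dermelm.synthetic import benign_spec, dice, generate_image


def brute_force_otsu(channel, n_bins=256):
    """Independent exhaustive between-class-variance argmax in exact
    integer arithmetic.

    With equal-width bins the bin centers are affine in the bin index, so
    the ranking of ``w1*w2*(m1-m2)^2`` over splits is identical whether
    means are taken over values or over bin indices; with raw counts it
    reduces to the exact rational ``(s1*n2 - s2*n1)^2 / (n1*n2)`` with
    integer ``n`` (counts) and ``s`` (index-weighted counts).  Exact
    arithmetic gives tie resolution (lowest split wins) that no float
    round-off can disturb.
    """
    from fractions import Fraction

    lo, hi = channel.min(), channel.max()
    hist, edges = np.histogram(channel.ravel(), bins=n_bins, range=(lo, hi))
    counts = [int(c) for c in hist]
    total_n = sum(counts)
    total_s = sum(k * c for k, c in enumerate(counts))
    best_k, best_sigma = None, Fraction(-1)
    n1 = s1 = 0
    for k in range(n_bins - 1):
        n1 += counts[k]
        s1 += k * counts[k]
        n2 = total_n - n1
        s2 = total_s - s1
        if n1 == 0 or n2 == 0:
            continue
        sigma = Fraction((s1 * n2 - s2 * n1) ** 2, n1 * n2)
        if sigma > best_sigma:
            best_sigma, best_k = sigma, k
    return edges[best_k + 1]


class TestColorConversion:
    def test_black_maps_to_origin(self):
        img = np.zeros((1, 1, 3))
        np.testing.assert_array_equal(rgb_to_xyz(img), np.zeros((1, 1, 3)))

    def test_white_is_achromatic(self):
        # each matrix row sums to 1 before the 1/0.17697 scale
        out = rgb_to_xyz(np.ones((1, 1, 3)))[0, 0]
        np.testing.assert_allclose(out, np.full(3, 1.0 / 0.17697), rtol=1e-4)

    def test_pure_red_luminance_one(self):
        out = rgb_to_xyz(np.array([[[1.0, 0.0, 0.0]]]))[0, 0]
        np.testing.assert_allclose(
            out, [0.49 / 0.17697, 1.0, 0.0], rtol=1e-10, atol=1e-12
        )

    def test_linearity(self, rng):
        img = rng.random((4, 4, 3))
        np.testing.assert_allclose(
            rgb_to_xyz(0.37 * img), 0.37 * rgb_to_xyz(img), rtol=1e-12
        )


class TestNormalizedChannels:
    def test_pure_red_pixel(self):
        rgb = np.array([[[1.0, 0.0, 0.0]]])
        rhat, _ = normalize_channels(rgb, rgb_to_xyz(rgb))
        assert rhat[0, 0] == 1.0

    def test_gray_pixel_intensity_invariant(self):
        for v in (0.2, 0.9):
            rgb = np.full((1, 1, 3), v)
            rhat, _ = normalize_channels(rgb, rgb_to_xyz(rgb))
            assert rhat[0, 0] == pytest.approx(1.0 / np.sqrt(3.0))

    def test_black_pixel_zero_by_convention(self):
        rgb = np.zeros((1, 1, 3))
        rhat, xhat = normalize_channels(rgb, rgb_to_xyz(rgb))
        assert rhat[0, 0] == 0.0 and xhat[0, 0] == 0.0

    def test_channels_in_unit_interval(self, rng):
        rgb = rng.random((16, 16, 3))
        rhat, xhat = normalize_channels(rgb, rgb_to_xyz(rgb))
        for ch in (rhat, xhat):
            assert ch.min() >= 0.0 and ch.max() <= 1.0 + 1e-12


class TestOtsu:
    def test_bimodal_split(self):
        channel = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)]).reshape(10, 10)
        t = otsu_threshold(channel)
        assert 0.1 < t < 0.9

    def test_constant_channel_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            otsu_threshold(np.full((5, 5), 0.5))

    @pytest.mark.parametrize("kind", ["uniform", "bimodal", "lognormal", "skewed"])
    def test_matches_exhaustive_oracle(self, kind):
        rng = np.random.default_rng(hash(kind) % 2**31)
        for _ in range(10):
            if kind == "uniform":
                ch = rng.random((24, 24))
            elif kind == "bimodal":
                ch = np.where(
                    rng.random((24, 24)) < 0.4,
                    rng.normal(0.25, 0.05, (24, 24)),
                    rng.normal(0.75, 0.08, (24, 24)),
                )
            elif kind == "lognormal":
                ch = rng.lognormal(0.0, 0.4, (24, 24))
            else:
                ch = rng.random((24, 24)) ** 3
            assert otsu_threshold(ch) == brute_force_otsu(ch)

    def test_unequal_mass_two_point(self):
        vals = np.concatenate([np.full(25, 0.2), np.full(75, 0.8)]).reshape(10, 10)
        assert otsu_threshold(vals) == brute_force_otsu(vals)

    def test_monotone_rebinning_invariance(self, rng):
        """A strictly monotone transform preserving bin membership keeps the
        chosen class split identical."""
        ch = rng.random((20, 20))
        t = otsu_threshold(ch, n_bins=16)
        below = ch <= t
        t2 = otsu_threshold(ch * 2.0 + 1.0, n_bins=16)
        np.testing.assert_array_equal(below, (ch * 2.0 + 1.0) <= t2)


class TestMorphology:
    def test_fill_closes_interior_hole(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:10, 2:10] = True
        mask[5, 5] = False
        out = morphology(mask, "fill", np.ones((3, 3), dtype=bool))
        assert out.sum() == mask.sum() + 1

    def test_open_removes_isolated_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        out = morphology(mask, "open", np.ones((3, 3), dtype=bool))
        assert not out.any()

    def test_close_idempotent_on_random_masks(self, rng):
        se = structuring_element("disk5")
        for _ in range(10):
            mask = rng.random((30, 30)) < 0.4
            once = morphology(mask, "close", se)
            twice = morphology(once, "close", se)
            np.testing.assert_array_equal(once, twice)

    def test_empty_se_rejected(self):
        with pytest.raises(ConfigError):
            morphology(np.ones((3, 3), dtype=bool), "open", np.zeros((3, 3), dtype=bool))

    def test_identity5_is_diagonal(self):
        np.testing.assert_array_equal(structuring_element("identity5"), np.eye(5, dtype=bool))


class TestSegment:
    def test_synthetic_disk_high_dice(self):
        img, truth, _ = generate_image(
            benign_spec(image_size=128, irregularity=0.0, asymmetry=0.0, noise_sigma=0.01),
            np.random.default_rng(5),
        )
        lesion = segment(denoise(img))
        assert dice(lesion.mask, truth) >= 0.95

    def test_single_connected_component(self, small_lesion_image):
        img, _, _ = small_lesion_image
        from skimage import measure

        mask = segment(img).mask
        assert measure.label(mask, connectivity=1).max() == 1

    def test_largest_component_kept(self):
        """Two lesions in frame: only the bigger one survives.

        The spurious blob is pasted off the main diagonal, where the
        default diagonal structuring element cannot chain it toward the
        true lesion.
        """
        rng = np.random.default_rng(2)
        img, truth, _ = generate_image(benign_spec(image_size=128), rng)
        img2 = img.copy()
        img2[8:14, 100:106] = np.array([0.30, 0.26, 0.24])
        mask = segment(img2).mask
        assert not mask[8:14, 100:106].any()
        assert dice(mask, truth) > 0.9

    def test_lesion_free_image_raises(self):
        """Skin with only isolated dark specks: opening empties the mask."""
        rng = np.random.default_rng(3)
        img = np.broadcast_to(np.array([0.8, 0.6, 0.5]), (64, 64, 3)).copy()
        img += rng.normal(0, 0.002, (64, 64, 3))
        for r, c in rng.integers(5, 59, (15, 2)):
            img[r, c] = [0.30, 0.26, 0.24]
        img = np.clip(img, 0, 1)
        with pytest.raises(DataError):
            segment(img)

    def test_thresholds_recorded_within_channel_range(self, small_lesion_image):
        img, _, _ = small_lesion_image
        lesion = segment(img)
        assert 0.0 < lesion.threshold_r < 1.0
        assert 0.0 < lesion.threshold_x < 1.0
        assert lesion.combine_rule == "and"
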