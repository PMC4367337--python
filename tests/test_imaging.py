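"""Blue-band extraction, histogram thresholding and binarization."""

import numpy as np
import pytest
from PIL import Image

from canopylai.imaging import (
    BlueBand,
    BlueHistogram,
    CanopyImage,
    ThresholdFallbackWarning,
    binarize,
    blue_histogram,
    extract_blue,
    find_threshold,
    load_image,
)


def _hist(counts_dict):
    counts = np.zeros(256, dtype=np.int64)
    for k, v in counts_dict.items():
        counts[k] = v
    return BlueHistogram(counts)


class TestLoadImage:
    def test_png_round_trip_identity(self, tmp_path, rng):
        pixels = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        path = tmp_path / "t1_1.png"
        Image.fromarray(pixels, "RGB").save(path)
        img = load_image(path)
        np.testing.assert_array_equal(img.pixels, pixels)
        assert img.source_id == "t1_1"

    def test_camera_resolution_preserved(self, tmp_path, rng):
        # the field protocol's 2048x1536 frames come through unresampled
        pixels = rng.integers(0, 256, size=(1536, 2048, 3), dtype=np.uint8)
        path = tmp_path / "full.jpg"
        Image.fromarray(pixels, "RGB").save(path, quality=90)
        img = load_image(path)
        assert (img.height_px, img.width_px) == (1536, 2048)

    def test_missing_file_raises_naming_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.png"):
            load_image(tmp_path / "nope.png")

    def test_grayscale_rejected(self, tmp_path):
        path = tmp_path / "gray.png"
        Image.fromarray(np.zeros((5, 5), dtype=np.uint8), "L").save(path)
        with pytest.raises(ValueError, match="RGB"):
            load_image(path)

    def test_undecodable_file_raises_oserror(self, tmp_path):
        path = tmp_path / "bad.png"
        path.write_bytes(b"not an image at all")
        with pytest.raises(OSError):
            load_image(path)


class TestExtractBlue:
    def test_uniform_blue_selected(self):
        img = CanopyImage(np.full((3, 3, 3), [10, 20, 30], dtype=np.uint8))
        band = extract_blue(img)
        assert (band.values == 30).all()

    def test_yellow_has_zero_blue(self):
        img = CanopyImage(np.full((2, 2, 3), [255, 255, 0], dtype=np.uint8))
        assert (extract_blue(img).values == 0).all()

    def test_matches_per_pixel_oracle(self, rng):
        pixels = rng.integers(0, 256, size=(13, 17, 3), dtype=np.uint8)
        band = extract_blue(CanopyImage(pixels))
        for r in range(13):
            for c in range(17):
                assert band.values[r, c] == pixels[r, c, 2]
        assert band.values.shape == pixels.shape[:2]


class TestBlueHistogram:
    def test_uniform_band(self):
        hist = blue_histogram(BlueBand(np.full((10, 10), 30, dtype=np.uint8)))
        assert hist.counts[30] == 100
        assert hist.total == 100
        assert (np.delete(hist.counts, 30) == 0).all()

    def test_two_tone_split(self):
        vals = np.concatenate([np.full(50, 10), np.full(50, 200)]).reshape(10, 10)
        hist = blue_histogram(BlueBand(vals.astype(np.uint8)))
        assert hist.counts[10] == 50 and hist.counts[200] == 50

    def test_matches_brute_force_tally(self, rng):
        vals = rng.integers(0, 256, size=(21, 19), dtype=np.uint8)
        hist = blue_histogram(BlueBand(vals))
        expected = np.zeros(256, dtype=int)
        for v in vals.ravel():
            expected[v] += 1
        np.testing.assert_array_equal(hist.counts, expected)
        assert hist.total == 21 * 19


class TestFindThreshold:
    def test_constructed_bimodal_valley_at_120(self):
        # piecewise-linear two-mode histogram, symmetric V around 120 within
        # more than a smoothing window, so the smoothed interior minimum
        # stays at 120 by construction
        counts = np.zeros(256, dtype=np.int64)
        for i in range(256):
            if 30 <= i <= 50:
                counts[i] = 100 + 10 * (i - 30)
            elif 50 < i <= 120:
                counts[i] = 300 - 4 * (i - 50)  # falls to 20 at 120
            elif 120 < i <= 200:
                counts[i] = 20 + 4 * (i - 120)
            elif 200 < i <= 220:
                counts[i] = 340 - 10 * (i - 200)
        counts[200] = 500  # sky mode clearly dominant
        assert find_threshold(BlueHistogram(counts)) == 120

    def test_degenerate_two_spike_plateau_midpoint(self):
        # only intensities 0 and 255: the valley is the whole zero plateau
        # between the smoothed spikes; the tie rule picks its midpoint
        assert find_threshold(_hist({0: 100, 255: 100})) == 127

    def test_two_tone_threshold_separates_tones(self, rng):
        for lo, hi in [(20, 200), (35, 185), (60, 150)]:
            n_lo = int(rng.integers(50, 500))
            n_hi = int(rng.integers(50, 500))
            t = find_threshold(_hist({lo: n_lo, hi: n_hi}))
            assert lo < t <= hi

    def test_unimodal_falls_back_to_otsu_with_warning(self):
        # single broad mode: no interior valley between two separated peaks
        counts = np.zeros(256, dtype=np.int64)
        for i in range(90, 170):
            counts[i] = 200 - abs(i - 130)
        hist = BlueHistogram(counts)
        with pytest.warns(ThresholdFallbackWarning):
            t = find_threshold(hist)
        # oracle: exhaustive between-class-variance search over all splits
        c = counts.astype(float)
        intens = np.arange(256.0)
        best, best_var = 0, -1.0
        for split in range(1, 256):
            w0, w1 = c[:split].sum(), c[split:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (c[:split] * intens[:split]).sum() / w0
            m1 = (c[split:] * intens[split:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_var, best = var, split
        # threshold_otsu returns a bin value; accept the split or its neighbour
        assert abs(t - best) <= 1

    def test_empty_histogram_errors(self):
        with pytest.raises(ValueError, match="empty"):
            find_threshold(BlueHistogram(np.zeros(256, dtype=np.int64)))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            find_threshold(_hist({10: 5, 200: 5}), smooth_window=8)


class TestBinarize:
    def test_all_foliage_below_threshold(self):
        band = BlueBand(np.full((5, 5), 30, dtype=np.uint8))
        mask = binarize(band, 120)
        assert mask.is_foliage.all() and mask.threshold_used == 120

    def test_all_sky_at_or_above_threshold(self):
        band = BlueBand(np.full((5, 5), 200, dtype=np.uint8))
        assert not binarize(band, 120).is_foliage.any()

    def test_threshold_value_itself_is_sky(self):
        band = BlueBand(np.full((2, 2), 120, dtype=np.uint8))
        assert not binarize(band, 120).is_foliage.any()

    def test_matches_per_pixel_oracle(self, rng):
        vals = rng.integers(0, 256, size=(15, 11), dtype=np.uint8)
        mask = binarize(BlueBand(vals), 97)
        expected = sum(1 for v in vals.ravel() if v < 97)
        assert mask.is_foliage.sum() == expected

    def test_monotone_in_threshold(self, rng):
        vals = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        band = BlueBand(vals)
        counts = [binarize(band, t).is_foliage.sum() for t in range(0, 256, 15)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_out_of_range_threshold_rejected(self):
        band = BlueBand(np.zeros((2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            binarize(band, 300)


def test_two_tone_pipeline_recovers_generated_mask(rng):
    """On synthetic two-tone images the automatic threshold lands strictly
    between the tones and binarization recovers the generated mask exactly."""
    for b1, b2 in [(20, 180), (50, 150), (10, 250)]:
        foliage = rng.random((40, 60)) < 0.6
        vals = np.where(foliage, b1, b2).astype(np.uint8)
        band = BlueBand(vals)
        t = find_threshold(blue_histogram(band))
        assert b1 < t <= b2
        np.testing.assert_array_equal(binarize(band, t).is_foliage, foliage)
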