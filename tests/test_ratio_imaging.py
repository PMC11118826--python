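"""Shift correction, pixel-wise ratio, clipping mask, weighted ROI traces."""

import io as _io
import struct
import zipfile

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioratio import synthetic_heart as sh
from cardioratio.ratio_imaging import (
    DualChannelMovie,
    Roi,
    apply_shift,
    compute_ratio_movie,
    estimate_pixel_shift,
    read_imagej_roi_zip,
    render_ratio_display,
    roi_weighted_ratio,
)


def _movie(num, den, dt=0.02):
    return DualChannelMovie(np.asarray(num, float), np.asarray(den, float), dt)


def _random_movie(rng, shape=(10, 16, 16)):
    num = rng.uniform(10, 500, size=shape)
    den = rng.uniform(10, 500, size=shape)
    return _movie(num, den)


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and loop-based)
# ---------------------------------------------------------------------------


def _oracle_ratio_and_mask(movie, display_range):
    lo, hi = display_range
    T, H, W = movie.numerator_stack.shape
    ratio = np.full((T, H, W), np.nan)
    valid = np.zeros((T, H, W), dtype=bool)
    for t in range(T):
        for y in range(H):
            for x in range(W):
                d = movie.denominator_stack[t, y, x]
                if d <= 0:
                    continue
                r = movie.numerator_stack[t, y, x] / d
                ratio[t, y, x] = r
                valid[t, y, x] = (lo / 4.0 <= r <= hi * 4.0)
    return ratio, valid


def _oracle_weighted_trace(ratio, valid, movie, mask):
    T = ratio.shape[0]
    out = np.full(T, np.nan)
    for t in range(T):
        acc_w = acc_wr = 0.0
        for y in range(mask.shape[0]):
            for x in range(mask.shape[1]):
                if mask[y, x] and valid[t, y, x]:
                    w = 0.5 * (
                        movie.numerator_stack[t, y, x]
                        + movie.denominator_stack[t, y, x]
                    )
                    acc_w += w
                    acc_wr += w * ratio[t, y, x]
        if acc_w > 0:
            out[t] = acc_wr / acc_w
    return out


class TestPixelShift:
    def test_identical_channels_give_zero_shift(self):
        rng = np.random.default_rng(0)
        num = rng.uniform(0, 100, size=(5, 20, 20))
        movie = _movie(num, num.copy())
        assert estimate_pixel_shift(movie, 4) == (0, 0)

    def test_exact_translation_recovery(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 100, size=(3, 30, 30))
        den = np.zeros_like(base)
        den[:, 2:, :27] = base[:, :-2, 3:]  # shift by (dy=2, dx=-3)
        movie = _movie(base, den)
        assert estimate_pixel_shift(movie, 4) == (2, -3)

    def test_synthetic_movie_shift_recovered_under_noise(self, noisy_movie):
        _, movie, _ = noisy_movie
        assert estimate_pixel_shift(movie, 5) == (1, 4)

    def test_flat_images_rejected(self):
        movie = _movie(np.ones((3, 8, 8)), np.ones((3, 8, 8)))
        with pytest.raises(ValueError, match="indeterminate"):
            estimate_pixel_shift(movie, 2)

    def test_apply_zero_shift_is_identity(self):
        rng = np.random.default_rng(2)
        movie = _random_movie(rng)
        out = apply_shift(movie, (0, 0))
        np.testing.assert_array_equal(
            out.denominator_stack, movie.denominator_stack
        )
        assert out.in_field().all()

    def test_shift_then_negation_restores_overlap(self):
        rng = np.random.default_rng(3)
        movie = _random_movie(rng)
        out = apply_shift(apply_shift(movie, (2, -1)), (-2, 1))
        region = out.in_field()
        np.testing.assert_array_equal(
            out.denominator_stack[:, region],
            movie.denominator_stack[:, region],
        )

    def test_correction_matches_unshifted_render(self):
        base = dict(shot_noise=False, background_level=0.0, duration=1.0)
        cfg0 = sh.scenario_preset("control", **base)
        cfg1 = sh.scenario_preset("control", channel_pixel_shift=(2, -3), **base)
        movie0, gt0 = sh.render_dual_channel_movie(cfg0)
        movie1, _ = sh.render_dual_channel_movie(cfg1)
        corrected = apply_shift(movie1, (2, -3))
        mask = gt0.chamber_masks_per_frame["ventricle"][0] & corrected.in_field()
        np.testing.assert_allclose(
            corrected.denominator_stack[:, mask],
            movie0.denominator_stack[:, mask],
            rtol=1e-12,
        )

    def test_oversize_shift_rejected(self):
        movie = _movie(np.ones((2, 8, 8)), np.ones((2, 8, 8)))
        with pytest.raises(ValueError):
            apply_shift(movie, (8, 0))


class TestRatioMovie:
    def test_simple_arithmetic_and_validity(self):
        movie = _movie([[[200.0]]], [[[100.0]]])
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        assert rm.ratio_stack[0, 0, 0] == pytest.approx(2.0)
        assert rm.valid_mask[0, 0, 0]

    def test_clipping_rule_low_side(self):
        # ratio 0.1 < 0.5/4 = 0.125 -> invalid
        movie = _movie([[[10.0]]], [[[100.0]]])
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        assert not rm.valid_mask[0, 0, 0]
        assert rm.clip_low == pytest.approx(0.125)
        assert rm.clip_high == pytest.approx(12.0)

    def test_nonpositive_denominator_invalid(self):
        movie = _movie([[[10.0, 10.0]]], [[[0.0, 5.0]]])
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        assert not rm.valid_mask[0, 0, 0]
        assert rm.valid_mask[0, 0, 1]

    def test_bad_display_range_rejected(self):
        movie = _movie([[[1.0]]], [[[1.0]]])
        with pytest.raises(ValueError):
            compute_ratio_movie(movie, (0.0, 3.0))

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(11)
        movie = _random_movie(rng)
        # sprinkle zero denominators and extreme ratios
        movie.denominator_stack[rng.random(movie.denominator_stack.shape) < 0.05] = 0.0
        movie.numerator_stack[rng.random(movie.numerator_stack.shape) < 0.05] *= 100
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        oracle_ratio, oracle_valid = _oracle_ratio_and_mask(movie, (0.5, 3.0))
        np.testing.assert_array_equal(rm.valid_mask, oracle_valid)
        np.testing.assert_array_equal(
            rm.ratio_stack[rm.valid_mask], oracle_ratio[oracle_valid]
        )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        gain=st.floats(0.01, 100.0),
        seed=st.integers(0, 10_000),
    )
    def test_ratio_invariant_under_gain_field(self, gain, seed):
        """Multiplying both channels by any positive gain field leaves the
        ratio stack unchanged wherever it is defined."""
        rng = np.random.default_rng(seed)
        movie = _random_movie(rng, shape=(3, 8, 8))
        field = gain * rng.uniform(0.5, 2.0, size=movie.numerator_stack.shape)
        scaled = _movie(
            movie.numerator_stack * field, movie.denominator_stack * field
        )
        r1 = compute_ratio_movie(movie, (0.5, 3.0))
        r2 = compute_ratio_movie(scaled, (0.5, 3.0))
        np.testing.assert_allclose(r1.ratio_stack, r2.ratio_stack, rtol=1e-12)


class TestRoi:
    def test_polygon_mask_by_pixel_center(self):
        roi = Roi.from_polygon(
            "sq", [(0.5, 0.5), (0.5, 3.5), (3.5, 3.5), (3.5, 0.5)], (6, 6)
        )
        assert roi.mask.sum() == 9  # centers 1..3 x 1..3
        assert roi.shoelace_area_px() == pytest.approx(9.0)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            Roi.from_polygon("line", [(0, 0), (0, 1)], (4, 4))

    def test_imagej_roi_zip_roundtrip(self, tmp_path):
        """A polygon ROI written in the ImageJ binary layout parses back."""
        xs, ys = [2, 10, 10, 2], [3, 3, 12, 12]
        top, left = min(ys), min(xs)
        header = bytearray(64)
        header[0:4] = b"Iout"
        struct.pack_into(">h", header, 4, 228)
        header[6] = 0  # polygon
        struct.pack_into(
            ">hhhhh", header, 8, top, left, max(ys), max(xs), len(xs)
        )
        body = b"".join(struct.pack(">h", x - left) for x in xs)
        body += b"".join(struct.pack(">h", y - top) for y in ys)
        path = tmp_path / "rois.zip"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("ventricle.roi", bytes(header) + body)
        rois = read_imagej_roi_zip(path, (20, 20))
        assert rois[0].label == "ventricle"
        np.testing.assert_array_equal(
            rois[0].polygon, [[3, 2], [3, 10], [12, 10], [12, 2]]
        )


class TestWeightedRoiTrace:
    def test_uniform_ratio_any_weights(self):
        num = np.full((4, 5, 5), 0.0)
        den = np.zeros_like(num)
        rng = np.random.default_rng(4)
        den[:] = rng.uniform(50, 150, size=den.shape)
        num[:] = 2.0 * den
        movie = _movie(num, den)
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        roi = Roi.from_polygon("r", [(-0.5, -0.5), (-0.5, 4.5), (4.5, 4.5), (4.5, -0.5)], (5, 5))
        trace = roi_weighted_ratio(rm, movie, roi)
        np.testing.assert_allclose(trace.values, 2.0, rtol=1e-12)

    def test_two_pixel_hand_example(self):
        # ratios {2, 1} with channel-mean weights {3, 1} -> (6+1)/4 = 1.75
        num = np.array([[[4.0, 1.0]]])
        den = np.array([[[2.0, 1.0]]])
        movie = _movie(num, den)
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        roi = Roi.from_polygon(
            "pair", [(-0.5, -0.5), (-0.5, 1.5), (0.5, 1.5), (0.5, -0.5)], (1, 2)
        )
        trace = roi_weighted_ratio(rm, movie, roi)
        assert trace.values[0] == pytest.approx(1.75)
        assert trace.n_valid_pixels_per_frame[0] == 2

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(5)
        movie = _random_movie(rng)
        movie.denominator_stack[rng.random(movie.denominator_stack.shape) < 0.1] = 0.0
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        roi = Roi.from_polygon(
            "blob", [(1.2, 1.8), (1.2, 12.0), (13.5, 7.0)], (16, 16)
        )
        trace = roi_weighted_ratio(rm, movie, roi)
        oracle_ratio, oracle_valid = _oracle_ratio_and_mask(movie, (0.5, 3.0))
        expected = _oracle_weighted_trace(oracle_ratio, oracle_valid, movie, roi.mask)
        # identical weights and terms; summation order may differ by a few ulp
        np.testing.assert_allclose(trace.values, expected, rtol=5e-15)

    def test_motion_cancellation_on_beating_heart(self, clean_movie):
        """Single-channel ROI intensity is modulated by the beat; the
        weighted ratio trace follows the Ca2+ signal to machine precision."""
        cfg, movie, gt = clean_movie
        roi = Roi.from_polygon(
            "ventricle", sh.chamber_polygon(cfg, "ventricle"), cfg.image_shape
        )
        den_mean = movie.denominator_stack[:, roi.mask].mean(axis=1)
        assert np.ptp(den_mean) / den_mean.max() >= 0.20
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        trace = roi_weighted_ratio(rm, movie, roi)
        np.testing.assert_allclose(
            trace.values, gt.true_ratio_trace["ventricle"], rtol=1e-12
        )

    def test_empty_roi_rejected(self):
        movie = _movie(np.ones((2, 4, 4)), np.ones((2, 4, 4)))
        rm = compute_ratio_movie(movie, (0.5, 3.0))
        roi = Roi.from_polygon("sq", [(0.6, 0.6), (0.6, 2.6), (2.6, 2.6), (2.6, 0.6)], (4, 4))
        roi.mask = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            roi_weighted_ratio(rm, movie, roi)


class TestDisplay:
    def _simple(self, num, den):
        movie = _movie(num, den)
        return movie, compute_ratio_movie(movie, (0.5, 3.0))

    def test_all_invalid_frame_is_dark(self):
        movie, rm = self._simple(np.ones((1, 3, 3)), np.zeros((1, 3, 3)))
        img = render_ratio_display(rm, movie, 0)
        np.testing.assert_array_equal(img, 0.0)

    def test_equal_ratio_different_intensity_same_hue(self):
        num = np.array([[[100.0, 10.0]]])
        den = np.array([[[100.0, 10.0]]])
        movie, rm = self._simple(num, den)
        img = render_ratio_display(rm, movie, 0)
        import matplotlib.colors as mc

        hsv = mc.rgb_to_hsv(img)
        assert hsv[0, 0, 0] == pytest.approx(hsv[0, 1, 0])
        assert hsv[0, 0, 2] > hsv[0, 1, 2]

    def test_display_clamps_below_range_to_same_hue(self):
        num = np.array([[[20.0, 40.0]]])   # ratios 0.2 and 0.4, both < 0.5
        den = np.array([[[100.0, 100.0]]])
        movie, rm = self._simple(num, den)
        img = render_ratio_display(rm, movie, 0)
        import matplotlib.colors as mc

        hsv = mc.rgb_to_hsv(img)
        assert hsv[0, 0, 0] == pytest.approx(hsv[0, 1, 0])
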