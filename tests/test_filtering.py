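"""Contrast and spatial-frequency manipulations: gains, RMS control, locality."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefilt.filtering import (
    BACKGROUND,
    CONTRAST,
    FOREGROUND,
    HIGHPASS,
    LOWPASS,
    FilterSeriesConfig,
    FilterStep,
    alpha_blend,
    butterworth_filter_image,
    butterworth_response,
    frequency_filter_region,
    log_spaced_cutoffs,
    make_filter_series,
    region_mask,
    rms_contrast,
)
from prefilt.stimuli import ForegroundMask, isolate_region, make_stimulus


class TestRmsContrast:
    def test_uniform_region_is_zero(self):
        px = np.full((8, 8), 0.3)
        assert rms_contrast(px, np.ones((8, 8), dtype=bool)) == 0.0

    def test_hand_computed_population_sd(self):
        px = np.zeros((2, 2))
        px.flat[:] = [0.2, 0.4, 0.6, 0.8]
        assert rms_contrast(px, np.ones((2, 2), dtype=bool)) == pytest.approx(
            0.2236, abs=1e-4
        )

    def test_two_point_set(self):
        px = np.array([[0.0, 1.0]])
        assert rms_contrast(px, np.ones((1, 2), dtype=bool)) == pytest.approx(0.5)

    def test_single_pixel_raises(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="< 2 pixels"):
            rms_contrast(np.zeros((4, 4)), mask)


class TestAlphaBlend:
    def test_alpha_one_is_identity(self, small_set):
        stimuli, masks = small_set
        out = alpha_blend(stimuli[0], masks[0], FOREGROUND, 1.0)
        assert np.array_equal(out.pixels, stimuli[0].pixels)

    def test_alpha_zero_removes_region(self, small_set):
        stimuli, masks = small_set
        out = alpha_blend(stimuli[0], masks[0], FOREGROUND, 0.0)
        target = region_mask(stimuli[0], masks[0], FOREGROUND)
        assert np.allclose(out.pixels[target], stimuli[0].background_gray)

    def test_linear_blend_arithmetic(self):
        px = np.full((16, 16), 0.8)
        stim = make_stimulus(px, 1.0, aperture_mask=np.ones((16, 16), dtype=bool))
        mask = ForegroundMask(np.ones((16, 16), dtype=bool))
        out = alpha_blend(stim, mask, FOREGROUND, 0.5)
        assert np.allclose(out.pixels, 0.65)

    def test_alpha_out_of_range_raises(self, small_set):
        stimuli, masks = small_set
        with pytest.raises(ValueError, match="alpha"):
            alpha_blend(stimuli[0], masks[0], FOREGROUND, 1.5)


class TestButterworthResponse:
    def test_gain_at_cutoff_both_modes(self):
        for mode in (LOWPASS, HIGHPASS):
            assert butterworth_response(2.0, 2.0, 5, mode) == pytest.approx(
                1 / np.sqrt(2), abs=1e-12
            )

    def test_lowpass_order5_at_twice_cutoff(self):
        assert butterworth_response(2.0, 1.0, 5, LOWPASS) == pytest.approx(
            1 / np.sqrt(1025), abs=1e-12
        )

    def test_dc_limits(self):
        assert butterworth_response(0.0, 1.0, 5, LOWPASS) == 1.0
        assert butterworth_response(0.0, 1.0, 5, HIGHPASS) == 0.0

    def test_power_complementarity_at_cutoff(self):
        lp = butterworth_response(3.0, 3.0, 5, LOWPASS)
        hp = butterworth_response(3.0, 3.0, 5, HIGHPASS)
        assert lp**2 + hp**2 == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        f=st.floats(0.0, 30.0),
        cutoff=st.floats(0.01, 30.0),
        order=st.integers(1, 8),
    )
    def test_gain_bounded_and_monotone_flanks(self, f, cutoff, order):
        lp = butterworth_response(f, cutoff, order, LOWPASS)
        hp = butterworth_response(f, cutoff, order, HIGHPASS)
        assert 0.0 <= lp <= 1.0 and 0.0 <= hp <= 1.0
        # lowpass decreases with f, highpass increases
        assert butterworth_response(f + 1.0, cutoff, order, LOWPASS) <= lp + 1e-12
        assert butterworth_response(f + 1.0, cutoff, order, HIGHPASS) >= hp - 1e-12


class TestCutoffSampling:
    def test_geometric_progression_endpoints_inclusive(self):
        cuts = log_spaced_cutoffs(0.05, 25.0, 4)
        assert np.allclose(cuts, [0.05, 0.39685, 3.14980, 25.0], atol=1e-4)
        ratio = (25.0 / 0.05) ** (1 / 3)
        assert np.allclose(cuts[1:] / cuts[:-1], ratio)


class TestFrequencyFilterRegion:
    def test_grating_attenuation_matches_analytic_gain(self):
        n = 128
        ppd = 25.0
        k = 8
        f0 = k / n  # cycles/pixel, FFT-aligned
        x = np.arange(n)
        grating = 0.5 + 0.25 * np.cos(2 * np.pi * f0 * x)[None, :] * np.ones((n, 1))
        filtered = butterworth_filter_image(grating, f0 * ppd, ppd, 5, LOWPASS)
        amp = lambda im: np.abs(np.fft.fft2(im)[0, k])
        ratio = amp(filtered) / amp(grating)
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_allpass_lowpass_is_near_identity(self, small_set):
        stimuli, masks = small_set
        stim = stimuli[0]
        step = FilterStep(LOWPASS, 1, 1e3 * stim.px_per_degree, BACKGROUND)
        out = frequency_filter_region(stim, masks[0], BACKGROUND, step)
        assert np.allclose(out.pixels, stim.pixels, atol=1e-9)

    def test_rms_preserved_pre_clipping(self, small_set):
        stimuli, masks = small_set
        for stim, mask in zip(stimuli[:4], masks[:4]):
            for mode in (LOWPASS, HIGHPASS):
                step = FilterStep(mode, 2, 0.39685, FOREGROUND)
                out = frequency_filter_region(stim, mask, FOREGROUND, step)
                assert abs(out.rms_after - out.rms_before) <= 1e-6

    def test_region_locality(self, small_set):
        stimuli, masks = small_set
        stim, mask = stimuli[1], masks[1]
        step = FilterStep(LOWPASS, 3, 0.2, FOREGROUND)
        out = frequency_filter_region(stim, mask, FOREGROUND, step)
        outside = ~region_mask(stim, mask, FOREGROUND)
        assert np.array_equal(out.pixels[outside], stim.pixels[outside])

    def test_uniform_region_returned_unchanged(self):
        px = np.full((64, 64), 0.5)
        px[40:50, 40:50] = np.linspace(0, 1, 100).reshape(10, 10)
        stim = make_stimulus(px, 3.2)
        mask = ForegroundMask(np.zeros((64, 64), dtype=bool) | (px != 0.5))
        # background within aperture is uniform -> unchanged, no error
        step = FilterStep(LOWPASS, 2, 0.4, BACKGROUND)
        out = frequency_filter_region(stim, mask, BACKGROUND, step)
        assert np.array_equal(out.pixels, stim.pixels)


class TestFilterSeries:
    def test_series_structure_and_monotone_parameters(self, small_set):
        stimuli, masks = small_set
        series = make_filter_series(stimuli[0], masks[0], BACKGROUND)
        assert len(series) == 12
        by_proc = {}
        for fs in series:
            by_proc.setdefault(fs.step.procedure, []).append(fs.step.parameter)
        assert by_proc[CONTRAST] == sorted(by_proc[CONTRAST], reverse=True)
        assert by_proc[LOWPASS] == sorted(by_proc[LOWPASS], reverse=True)
        assert by_proc[HIGHPASS] == sorted(by_proc[HIGHPASS])

    def test_contrast_endpoint_equals_region_complement(self, small_set):
        stimuli, masks = small_set
        stim, mask = stimuli[2], masks[2]
        series = make_filter_series(stim, mask, BACKGROUND)
        alpha0 = [fs for fs in series if fs.step.procedure == CONTRAST][-1]
        assert alpha0.step.parameter == 0.0
        fg_only = isolate_region(stim, mask, FOREGROUND)
        assert np.allclose(alpha0.pixels, fg_only.pixels, atol=1e-12)

    def test_untargeted_region_bit_identical_across_all_steps(self, small_set):
        stimuli, masks = small_set
        stim, mask = stimuli[3], masks[3]
        outside = ~region_mask(stim, mask, FOREGROUND)
        for fs in make_filter_series(stim, mask, FOREGROUND):
            assert np.array_equal(fs.pixels[outside], stim.pixels[outside])

    def test_l2_distance_monotone_in_strength(self, small_set):
        """Stronger filtering moves the image monotonically away from intact."""
        stimuli, masks = small_set
        stim, mask = stimuli[4], masks[4]
        series = make_filter_series(stim, mask, BACKGROUND)
        for proc in (CONTRAST, LOWPASS, HIGHPASS):
            dists = [
                np.linalg.norm(fs.pixels - stim.pixels)
                for fs in series
                if fs.step.procedure == proc
            ]
            assert all(b >= a - 1e-9 for a, b in zip(dists, dists[1:])), (proc, dists)
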