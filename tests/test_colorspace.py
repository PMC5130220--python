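"""Frequency -> RGB -> HSL conversion against independent oracles.

The hue/saturation oracle is the stdlib ``colorsys`` HLS implementation on
unit-scaled components, which is the textbook 8-bit HSL up to scaling.
"""

import colorsys

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from bleedcap import (
    CalibrationError,
    HSColor,
    RGBComponents,
    ReadingError,
    SensorReading,
    WhiteBalance,
    calibrate_white_balance,
    frequencies_to_rgb,
    reading_to_hs,
    rgb_to_hsl,
)
from bleedcap.colorspace import hsl_arrays

positive_freq = st.floats(min_value=1e-3, max_value=1e3)
component = st.floats(min_value=0.0, max_value=255.0)


def reading(fr, fg, fb, t=0.0, v=3.0):
    return SensorReading(t=t, f_red=fr, f_green=fg, f_blue=fb, voltage=v)


class TestCalibration:
    def test_recovers_reference_integration_times(self):
        """A white reference at the sensor's nominal frequencies yields the
        reference unit's printed integration times (t = 255 / f)."""
        wb = calibrate_white_balance(reading(3.1323, 4.1431, 4.7136))
        assert wb.t_red == pytest.approx(81.41, abs=0.005)
        assert wb.t_green == pytest.approx(61.55, abs=0.005)
        assert wb.t_blue == pytest.approx(54.10, abs=0.005)

    def test_identity_scaling(self):
        wb = calibrate_white_balance(reading(255.0, 255.0, 255.0))
        assert wb.times == (1.0, 1.0, 1.0)

    def test_zero_frequency_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_white_balance(reading(0.0, 1.0, 1.0))

    def test_white_maps_to_full_scale(self):
        white = reading(2.5, 3.5, 4.5)
        rgb = frequencies_to_rgb(white, calibrate_white_balance(white))
        assert (rgb.red, rgb.green, rgb.blue) == pytest.approx((255.0,) * 3)

    @given(fr=positive_freq, fg=positive_freq, fb=positive_freq)
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_is_achromatic(self, fr, fg, fb):
        """Any positive white reading converts to an achromatic color under
        its own calibration."""
        white = reading(fr, fg, fb)
        color = reading_to_hs(white, calibrate_white_balance(white))
        assert color.achromatic
        assert color.saturation == 0.0
        assert color.hue == 0.0


class TestFrequenciesToRgb:
    def test_undiluted_blood_components(self, wb):
        rgb = frequencies_to_rgb(reading(1.7325, 0.6087, 0.5918), wb)
        assert rgb.red == pytest.approx(141.04, abs=0.01)
        assert rgb.green == pytest.approx(37.46, abs=0.01)
        assert rgb.blue == pytest.approx(32.02, abs=0.01)

    def test_colorless_juice_is_near_white(self, wb):
        rgb = frequencies_to_rgb(reading(3.0148, 3.9876, 4.4974), wb)
        assert rgb.red == pytest.approx(245.4, abs=0.1)
        assert rgb.green == pytest.approx(245.4, abs=0.1)
        assert rgb.blue == pytest.approx(243.3, abs=0.1)

    def test_zero_frequencies_give_black(self, wb):
        rgb = frequencies_to_rgb(reading(0.0, 0.0, 0.0), wb)
        assert (rgb.red, rgb.green, rgb.blue) == (0.0, 0.0, 0.0)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ReadingError):
            reading(-1.0, 1.0, 1.0)

    @given(f=positive_freq, c=st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=50)
    def test_linearity_per_channel(self, wb, f, c):
        base = frequencies_to_rgb(reading(f, f, f), wb)
        scaled = frequencies_to_rgb(reading(c * f, f, f), wb)
        assert scaled.red == pytest.approx(c * base.red, rel=1e-12)
        assert scaled.green == base.green


class TestRgbToHsl:
    @pytest.mark.parametrize(
        "rgb, h_expected, s_expected",
        [
            ((141.04, 37.46, 32.02), 3, 0.63),   # undiluted blood
            ((206.06, 173.92, 157.86), 20, 0.33),  # 64-fold dilution
            ((255.0, 0.0, 0.0), 0, 1.0),          # pure red limit
        ],
    )
    def test_reference_points(self, rgb, h_expected, s_expected):
        color = rgb_to_hsl(RGBComponents(*rgb))
        h, s = color.rounded()
        assert h == h_expected
        assert s == pytest.approx(s_expected, abs=0.005)

    @given(x=component)
    @settings(derandomize=True, max_examples=50)
    def test_gray_axis_is_achromatic(self, x):
        color = rgb_to_hsl(RGBComponents(x, x, x))
        assert color.achromatic and color.saturation == 0.0

    @given(r=component, g=component, b=component)
    @settings(derandomize=True, max_examples=300)
    def test_hue_and_saturation_ranges(self, r, g, b):
        color = rgb_to_hsl(RGBComponents(r, g, b))
        assert 0.0 <= color.hue < 360.0
        assert 0.0 <= color.saturation <= 1.0

    @given(
        r=component, g=component, b=component,
        c=st.floats(min_value=0.1, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_hue_scale_invariance(self, r, g, b, c):
        """Multiplying all components by c > 0 leaves the hue unchanged."""
        assume(max(r, g, b) - min(r, g, b) > 1e-2)  # avoid float blow-up near gray
        h1 = rgb_to_hsl(RGBComponents(r, g, b)).hue
        h2 = rgb_to_hsl(RGBComponents(c * r, c * g, c * b)).hue
        delta = abs(h1 - h2)
        assert min(delta, 360.0 - delta) < 1e-6  # circular comparison


    def test_oracle_equivalence_on_8bit_grid(self):
        """H and S agree with the textbook HSL formulas (via colorsys) on a
        grid of 8-bit RGB triples."""
        grid = list(range(0, 256, 17)) + [1, 254]
        for r in grid:
            for g in grid:
                for b in grid:
                    color = rgb_to_hsl(RGBComponents(float(r), float(g), float(b)))
                    oh, ol, os = colorsys.rgb_to_hls(r / 255.0, g / 255.0, b / 255.0)
                    if r == g == b:
                        assert color.achromatic
                        continue
                    assert color.hue == pytest.approx((oh * 360.0) % 360.0, abs=1e-9)
                    assert color.saturation == pytest.approx(os, abs=1e-9)


class TestVectorizedHsl:
    @given(
        st.lists(
            st.tuples(component, component, component), min_size=1, max_size=30
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_matches_scalar_conversion(self, triples):
        arr = np.array(triples, dtype=float)
        h, s, l = hsl_arrays(arr[:, 0], arr[:, 1], arr[:, 2])
        for i, (r, g, b) in enumerate(triples):
            ref = rgb_to_hsl(RGBComponents(r, g, b))
            assert h[i] == pytest.approx(ref.hue, abs=1e-9)
            assert s[i] == pytest.approx(ref.saturation, abs=1e-9)
            assert l[i] == pytest.approx(ref.lightness, abs=1e-9)


class TestTableReproduction:
    def test_reproducible_rows_match_reported_values(self, wb, solutions):
        """Rows 2-7, 9, 10 of the dilution series reproduce their reported
        H (±0.5 deg before rounding) and S (±0.005 before rounding)."""
        for sol in solutions:
            if sol.number in (1, 8):
                continue
            color = reading_to_hs(sol.reading(), wb)
            assert abs(color.hue - sol.reported_h) < 0.5, sol.label
            assert abs(color.saturation - sol.reported_s) < 0.005, sol.label

    def test_known_inconsistent_rows_stay_inconsistent(self, wb, solutions):
        """Rows 1 and 8 carry reported H/S that do not follow from their own
        frequency columns (probable transcription errors); assert the
        discrepancy so a formula change that 'fixes' them is flagged."""
        row1 = reading_to_hs(solutions[0].reading(), wb)
        assert row1.saturation == pytest.approx(0.454, abs=0.005)  # reported 0.33
        row8 = reading_to_hs(solutions[7].reading(), wb)
        assert row8.hue == pytest.approx(358.93, abs=0.05)  # reported 9
        assert row8.saturation == pytest.approx(0.403, abs=0.005)  # reported 0.51
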