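"""Sensor frequency -> RGB -> HSL conversion.

The capsule's color sensor reports, for each of its red/green/blue filter
channels, a square-wave frequency proportional to the reflected light
intensity.  A white-balance calibration assigns each channel an integration
time ``t_C`` (ms) such that a white reference maps to the nominal 8-bit
component 255; an arbitrary reading then converts to RGB components

    C = f_C [kHz] * t_C [ms]        (dimensionless counts, ~0-255)

and from there to HSL color features.  The HSL variant used here is the
standard 8-bit form: lightness ``L = (m + n) / 2`` on the 0-255 scale with
branch point 128, where ``m``/``n`` are the max/min RGB component,

    S = (m - n) / (m + n)           if L < 128
    S = (m - n) / (510 - (m + n))   if L >= 128

and hue is the usual 60-degree sector formula keyed on which channel attains
the maximum, wrapped into [0, 360).  Only H and S carry the diagnostic
signal (red-ness of the dyed film); L is computed but ignored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ReadingError

__all__ = [
    "SensorReading",
    "WhiteBalance",
    "RGBComponents",
    "HSColor",
    "DEFAULT_WHITE_BALANCE",
    "calibrate_white_balance",
    "frequencies_to_rgb",
    "rgb_to_hsl",
    "reading_to_hs",
    "hsl_arrays",
]

#: Nominal full-scale component value for a white reference.
WHITE_LEVEL = 255.0

#: Lightness branch point of the 8-bit saturation formula.
L_BRANCH = 128.0


@dataclass(frozen=True)
class SensorReading:
    """One timestamped observation from the capsule's color sensor.

    Parameters
    ----------
    t : float
        Time since capsule activation, seconds.
    f_red, f_green, f_blue : float
        Mean channel frequencies, kHz.  Non-negative.
    voltage : float
        Supply voltage at sampling time, volts.
    """

    t: float
    f_red: float
    f_green: float
    f_blue: float
    voltage: float = 3.0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ReadingError(f"negative timestamp: {self.t}")
        if min(self.f_red, self.f_green, self.f_blue) < 0:
            raise ReadingError(
                f"negative channel frequency: "
                f"({self.f_red}, {self.f_green}, {self.f_blue})"
            )
        if self.voltage < 0:
            raise ReadingError(f"negative supply voltage: {self.voltage}")

    @property
    def frequencies(self) -> tuple[float, float, float]:
        return (self.f_red, self.f_green, self.f_blue)


@dataclass(frozen=True)
class WhiteBalance:
    """Per-channel integration times (ms) mapping kHz to 8-bit counts."""

    t_red: float
    t_green: float
    t_blue: float

    def __post_init__(self) -> None:
        if min(self.t_red, self.t_green, self.t_blue) <= 0:
            raise CalibrationError(
                f"integration times must be strictly positive: "
                f"({self.t_red}, {self.t_green}, {self.t_blue})"
            )

    @property
    def times(self) -> tuple[float, float, float]:
        return (self.t_red, self.t_green, self.t_blue)


#: Calibration constants of the reference sensor unit (ms per channel).
DEFAULT_WHITE_BALANCE = WhiteBalance(t_red=81.4097, t_green=61.5481, t_blue=54.0988)


@dataclass(frozen=True)
class RGBComponents:
    """White-balanced trichromatic components on a nominal 0-255 scale.

    Components are not clamped: a reading brighter than the white reference
    legitimately yields a component above 255 and flows through the HSL
    formulas unchanged.
    """

    red: float
    green: float
    blue: float

    def __post_init__(self) -> None:
        if min(self.red, self.green, self.blue) < 0:
            raise ReadingError(
                f"negative RGB component: ({self.red}, {self.green}, {self.blue})"
            )


@dataclass(frozen=True)
class HSColor:
    """Hue/saturation/lightness color features of one observation.

    ``hue`` is in degrees in [0, 360), ``saturation`` in [0, 1], and
    ``lightness`` on the 0-255 component scale.  ``achromatic`` is set when
    all three RGB components coincide, in which case hue and saturation are
    pinned to 0 (the hue sector is undefined there).
    """

    hue: float
    saturation: float
    lightness: float
    achromatic: bool = False

    def rounded(self) -> tuple[int, float]:
        """Presentation rounding: hue to nearest degree, S to 2 decimals."""
        return (int(round(self.hue)), round(self.saturation, 2))


def calibrate_white_balance(white: SensorReading) -> WhiteBalance:
    """Derive per-channel integration times from a white-reference reading.

    Chooses ``t_C = 255 / f_C`` (ms, with f in kHz) so that the reference
    itself maps exactly to components (255, 255, 255).
    """
    if min(white.frequencies) <= 0:
        raise CalibrationError(
            "white reference must have strictly positive frequencies, "
            f"got {white.frequencies}"
        )
    tr, tg, tb = (WHITE_LEVEL / f for f in white.frequencies)
    return WhiteBalance(t_red=tr, t_green=tg, t_blue=tb)


def frequencies_to_rgb(reading: SensorReading, wb: WhiteBalance) -> RGBComponents:
    """Apply the white-balance calibration: ``C = f_C * t_C`` per channel."""
    fr, fg, fb = reading.frequencies
    return RGBComponents(red=fr * wb.t_red, green=fg * wb.t_green, blue=fb * wb.t_blue)


def rgb_to_hsl(rgb: RGBComponents) -> HSColor:
    """Convert 0-255-scale RGB components to HSL color features.

    Uses the 8-bit HSL form with the lightness-branched saturation and the
    60-degree hue sector formula; ties for the maximum channel resolve in
    R, G, B order.  Negative sector values wrap modulo 360.
    """
    r, g, b = rgb.red, rgb.green, rgb.blue
    m = max(r, g, b)
    n = min(r, g, b)
    lightness = (m + n) / 2.0
    d = m - n
    # relative epsilon: float rounding in the calibration round-trip leaves
    # d ~ 1e-13 on nominally equal components, which would otherwise hit the
    # 510-(m+n) singularity at pure white
    if d <= 1e-9 * max(m, 1.0):
        return HSColor(hue=0.0, saturation=0.0, lightness=lightness, achromatic=True)
    if lightness < L_BRANCH:
        s = d / (m + n)
    else:
        s = d / (2.0 * WHITE_LEVEL - (m + n))
    if r == m:
        h = 60.0 * ((g - b) / d)
    elif g == m:
        h = 60.0 * (2.0 + (b - r) / d)
    else:
        h = 60.0 * (4.0 + (r - g) / d)
    return HSColor(hue=h % 360.0, saturation=s, lightness=lightness)


def reading_to_hs(reading: SensorReading, wb: WhiteBalance) -> HSColor:
    """Full conversion: channel frequencies -> RGB counts -> HSL features."""
    return rgb_to_hsl(frequencies_to_rgb(reading, wb))


def hsl_arrays(
    red: np.ndarray, green: np.ndarray, blue: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized HSL conversion for rasters of 0-255-scale components.

    Returns ``(hue, saturation, lightness)`` arrays with the same semantics
    as :func:`rgb_to_hsl`; achromatic pixels get hue 0 and saturation 0.
    """
    r = np.asarray(red, dtype=float)
    g = np.asarray(green, dtype=float)
    b = np.asarray(blue, dtype=float)
    m = np.maximum(np.maximum(r, g), b)
    n = np.minimum(np.minimum(r, g), b)
    lightness = (m + n) / 2.0
    d = m - n
    chromatic = d > 1e-9 * np.maximum(m, 1.0)
    safe_d = np.where(chromatic, d, 1.0)

    denom = np.where(lightness < L_BRANCH, m + n, 2.0 * WHITE_LEVEL - (m + n))
    sat = np.where(chromatic, d / np.where(denom == 0, 1.0, denom), 0.0)

    hue_r = 60.0 * ((g - b) / safe_d)
    hue_g = 60.0 * (2.0 + (b - r) / safe_d)
    hue_b = 60.0 * (4.0 + (r - g) / safe_d)
    hue = np.select([r == m, g == m], [hue_r, hue_g], default=hue_b)
    hue = np.where(chromatic, hue % 360.0, 0.0)
    return hue, sat, lightness
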