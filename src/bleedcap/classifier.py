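"""Bleeding classification from H/S color features.

A dyed adsorptive film observed through the capsule's sensor is called
"bleeding" when its hue and saturation fall in a calibrated target region
of the H/S plane.  Hue near 0/360 with moderate-to-high saturation means
red; the calibrated default region is the rectangle

    3 <= H <= 25    and    0.3 <= S <= 0.8

(all bounds inclusive), which was chosen so that blood diluted up to
64-fold classifies as bleeding while simulated intestinal juices and
dilutions of 128-fold and beyond do not.  Because hue is circular, the
generic region form [0, H0] U [H1, 360] with S >= S0 is also supported via
a wraparound flag.

Severity grading subdivides the bleeding region by hue: lower hue (deeper
red, higher hemoglobin) is more severe.  The tier cut-points are explicit
configuration; the defaults place undiluted and 4-fold blood in the
``large`` tier, 16/32-fold in ``small``, and 64-fold in ``trace``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .colorspace import HSColor, hsl_arrays
from .errors import ConfigError, FormatError

__all__ = [
    "TargetArea",
    "Severity",
    "SeverityBands",
    "BleedingCall",
    "DEFAULT_TARGET_AREA",
    "DEFAULT_SEVERITY_BANDS",
    "is_bleeding",
    "grade_severity",
    "classify_image",
]


@dataclass(frozen=True)
class TargetArea:
    """H/S decision region for bleeding.

    In the default (non-wraparound) form the hue test is
    ``h_low <= H <= h_high``.  With ``wraparound=True`` the region is the
    complementary arc ``H <= h_low or H >= h_high`` (the [0, H0] U [H1, 360]
    form), so ``h_low`` plays the role of H0 and ``h_high`` of H1.
    The saturation test is always ``s_low <= S <= s_high``.
    """

    h_low: float = 3.0
    h_high: float = 25.0
    s_low: float = 0.3
    s_high: float = 0.8
    wraparound: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_low <= self.s_high <= 1.0):
            raise ConfigError(
                f"saturation bounds must satisfy 0 <= s_low <= s_high <= 1, "
                f"got [{self.s_low}, {self.s_high}]"
            )
        if not (0.0 <= self.h_low <= 360.0 and 0.0 <= self.h_high <= 360.0):
            raise ConfigError("hue bounds must lie in [0, 360]")
        if not self.wraparound and self.h_low > self.h_high:
            raise ConfigError(
                f"h_low {self.h_low} > h_high {self.h_high} without wraparound"
            )

    def contains_hue(self, h: float) -> bool:
        if self.wraparound:
            return h <= self.h_low or h >= self.h_high
        return self.h_low <= h <= self.h_high


#: Calibrated default decision region.
DEFAULT_TARGET_AREA = TargetArea()


class Severity(enum.Enum):
    """Graded amount of blood inferred from hue within the target region."""

    NONE = "none"
    TRACE = "trace"
    SMALL = "small"
    LARGE = "large"

    @property
    def rank(self) -> int:
        return ("none", "trace", "small", "large").index(self.value)


@dataclass(frozen=True)
class SeverityBands:
    """Hue cut-points partitioning the bleeding region into tiers.

    ``cuts = (c1, c2)`` with c1 < c2 gives: H <= c1 -> large,
    c1 < H <= c2 -> small, H > c2 -> trace.  Lower hue is deeper red and
    therefore more severe.
    """

    cuts: tuple[float, float] = (8.0, 15.0)

    def __post_init__(self) -> None:
        if len(self.cuts) != 2 or not self.cuts[0] < self.cuts[1]:
            raise ConfigError(
                f"severity cuts must be two strictly increasing hues, got {self.cuts}"
            )

    def tier(self, h: float) -> Severity:
        if h <= self.cuts[0]:
            return Severity.LARGE
        if h <= self.cuts[1]:
            return Severity.SMALL
        return Severity.TRACE


DEFAULT_SEVERITY_BANDS = SeverityBands()


@dataclass(frozen=True)
class BleedingCall:
    """Result of classifying one observation."""

    bleeding: bool
    severity: Severity
    h: float
    s: float

    def __post_init__(self) -> None:
        if self.bleeding != (self.severity is not Severity.NONE):
            raise ConfigError("severity must be none iff not bleeding")


def is_bleeding(color: HSColor, area: TargetArea = DEFAULT_TARGET_AREA) -> bool:
    """Membership test of (H, S) in the target region; L is never consulted."""
    return area.contains_hue(color.hue) and (
        area.s_low <= color.saturation <= area.s_high
    )


def grade_severity(
    color: HSColor,
    area: TargetArea = DEFAULT_TARGET_AREA,
    bands: SeverityBands = DEFAULT_SEVERITY_BANDS,
) -> BleedingCall:
    """Classify one observation and grade its severity by hue band."""
    if not is_bleeding(color, area):
        return BleedingCall(False, Severity.NONE, color.hue, color.saturation)
    return BleedingCall(True, bands.tier(color.hue), color.hue, color.saturation)


def classify_image(
    pixels: np.ndarray, area: TargetArea = DEFAULT_TARGET_AREA
) -> tuple[np.ndarray, float]:
    """Per-pixel bleeding classification of an RGB raster.

    Parameters
    ----------
    pixels : ndarray
        Array of shape (..., 3) with components on the 0-255 scale.
    area : TargetArea
        Decision region applied to each pixel's H/S features.

    Returns
    -------
    mask : boolean ndarray of shape ``pixels.shape[:-1]``
    fraction : float
        Mean of the mask (fraction of bleeding-colored pixels).
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim < 2 or arr.shape[-1] != 3 or arr.size == 0:
        raise FormatError(
            f"expected a nonempty raster with trailing RGB axis, got shape {arr.shape}"
        )
    h, s, _ = hsl_arrays(arr[..., 0], arr[..., 1], arr[..., 2])
    if area.wraparound:
        hue_ok = (h <= area.h_low) | (h >= area.h_high)
    else:
        hue_ok = (h >= area.h_low) & (h <= area.h_high)
    mask = hue_ok & (s >= area.s_low) & (s <= area.s_high)
    return mask, float(mask.mean())
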