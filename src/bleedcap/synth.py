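"""Synthetic sensor streams with the structure of the dilution series.

The generator emulates what the capsule's sensor would report while the
film is dyed by mixtures of intestinal juice and blood at a given
fold-dilution P.  Noise-free channel frequencies come from channel-wise
linear interpolation in log2(P) between the measured dilution anchors
(P = 512 down to 1); the dilution series was produced by double dilution,
so log2(P) is the natural axis and anchors are reproduced exactly.
Extrapolation outside [1, 512] is refused.  The 16-fold measurement is
excluded from the anchor set as inconsistent with the monotone trend (see
:mod:`bleedcap.reference`); that dilution is interpolated from its
neighbors.

Measurement noise is multiplicative lognormal, independent per channel,
parameterized by its coefficient of variation (default 2%, a stand-in: the
reference measurements report only means).  The lognormal is mean-one so
noisy frequencies are unbiased.

A scenario (duration, baseline juice, bleed episodes, voltage decay) turns
into one reading per duty-cycle period after the dormancy interval, plus a
per-reading ground-truth table for evaluating the classifier downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capsule import CapsuleConfig
from .colorspace import SensorReading
from .errors import ScenarioError
from .reference import CONSISTENT_DILUTION_ANCHORS, JUICE_ANCHORS

__all__ = [
    "BleedEpisode",
    "ScenarioSpec",
    "frequencies_for_dilution",
    "generate_stream",
    "readings_from_frame",
]

DEFAULT_NOISE_CV = 0.02

_LOG2_P = np.array(sorted(math.log2(p) for p in CONSISTENT_DILUTION_ANCHORS))
_ANCHOR_F = np.array(
    [CONSISTENT_DILUTION_ANCHORS[2.0**lp] for lp in _LOG2_P]
)  # shape (n_anchors, 3), ascending in P


@dataclass(frozen=True)
class BleedEpisode:
    """A bleeding interval: between ``start`` and ``end`` (s) the film sees
    blood at fold-dilution ``dilution``."""

    start: float
    end: float
    dilution: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ScenarioError(f"episode must have start < end, got [{self.start}, {self.end}]")
        if not 1.0 <= self.dilution <= 512.0:
            raise ScenarioError(f"episode dilution {self.dilution} outside [1, 512]")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic capsule run."""

    duration_s: float
    baseline: str = "juice2"
    episodes: tuple[BleedEpisode, ...] = ()
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int | None = None
    v_start: float = 3.0
    v_decay_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ScenarioError("duration must be positive")
        if self.baseline not in JUICE_ANCHORS:
            raise ScenarioError(
                f"unknown baseline {self.baseline!r}; choose from {sorted(JUICE_ANCHORS)}"
            )
        if self.noise_cv < 0:
            raise ScenarioError("noise CV must be non-negative")
        if self.noise_cv > 0 and self.seed is None:
            raise ScenarioError("noisy generation requires an explicit integer seed")
        eps = sorted(self.episodes, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise ScenarioError(
                    f"overlapping episodes: [{a.start}, {a.end}] and [{b.start}, {b.end}]"
                )
        for e in eps:
            if e.end > self.duration_s:
                raise ScenarioError(f"episode [{e.start}, {e.end}] exceeds duration")

    def dilution_at(self, t: float) -> float | None:
        for e in self.episodes:
            if e.start <= t < e.end:
                return e.dilution
        return None


def _noise_factors(cv: float, rng: np.random.Generator | None, n: int = 3) -> np.ndarray:
    """Mean-one lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    if rng is None:
        raise ScenarioError("noisy generation requires a random generator")
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def frequencies_for_dilution(
    dilution: float,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Channel frequencies (kHz) for blood at the given fold-dilution.

    Interpolates linearly in log2(dilution) between the measured anchors;
    anchor dilutions reproduce their measured frequencies exactly when
    ``noise_cv`` is 0.  Dilutions outside [1, 512] raise rather than
    extrapolate.
    """
    if not 1.0 <= dilution <= 512.0:
        raise ScenarioError(f"dilution {dilution} outside anchored range [1, 512]")
    lp = math.log2(dilution)
    clean = np.array(
        [np.interp(lp, _LOG2_P, _ANCHOR_F[:, c]) for c in range(3)]
    )
    fr, fg, fb = clean * _noise_factors(noise_cv, rng)
    return (float(fr), float(fg), float(fb))


def _baseline_frequencies(
    spec: ScenarioSpec, rng: np.random.Generator | None
) -> tuple[float, float, float]:
    clean = np.array(JUICE_ANCHORS[spec.baseline])
    fr, fg, fb = clean * _noise_factors(spec.noise_cv, rng)
    return (float(fr), float(fg), float(fb))


def generate_stream(
    spec: ScenarioSpec, cfg: CapsuleConfig = CapsuleConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a readings table and its ground truth for one scenario.

    Sample times start when dormancy elapses and repeat once per duty-cycle
    period until ``duration_s``.  During a bleed episode frequencies come
    from the episode's dilution; otherwise from the baseline juice anchor.
    Voltage decays linearly from ``v_start`` at ``v_decay_per_h`` volts per
    hour (floored at 0).

    Returns
    -------
    readings : DataFrame
        Columns ``t_s, f_red_khz, f_green_khz, f_blue_khz, voltage_v``.
    truth : DataFrame
        Columns ``t_s, true_dilution, true_bleeding`` (dilution empty
        outside episodes).
    """
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    times = np.arange(cfg.dormancy_s, spec.duration_s + 1e-9, cfg.period_s)
    rows, truth_rows = [], []
    for t in times:
        p = spec.dilution_at(float(t))
        if p is None:
            fr, fg, fb = _baseline_frequencies(spec, rng)
        else:
            fr, fg, fb = frequencies_for_dilution(p, spec.noise_cv, rng)
        v = max(0.0, spec.v_start - spec.v_decay_per_h * t / 3600.0)
        rows.append((float(t), fr, fg, fb, v))
        truth_rows.append((float(t), p, p is not None))
    readings = pd.DataFrame(
        rows, columns=["t_s", "f_red_khz", "f_green_khz", "f_blue_khz", "voltage_v"]
    )
    truth = pd.DataFrame(truth_rows, columns=["t_s", "true_dilution", "true_bleeding"])
    return readings, truth


def readings_from_frame(frame: pd.DataFrame) -> list[SensorReading]:
    """Convert a readings table to SensorReading objects."""
    return [
        SensorReading(
            t=row.t_s,
            f_red=row.f_red_khz,
            f_green=row.f_green_khz,
            f_blue=row.f_blue_khz,
            voltage=row.voltage_v,
        )
        for row in frame.itertuples(index=False)
    ]
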