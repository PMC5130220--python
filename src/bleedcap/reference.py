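"""Reference dilution-series measurements of the capsule's sensor.

Ten solutions were measured with the reference sensor unit: two simulated
intestinal juices (solution 1 transparent yellow, solution 2 colorless) and
eight double-dilutions of whole blood (hemoglobin 152 g/L) from 512-fold
down to undiluted.  Each entry carries the mean channel frequencies (kHz)
and the hue/saturation values reported for that solution.

These rows are the package's ground truth: the blood rows anchor the
synthetic dilution generator, and the juice rows provide non-bleeding
baselines.  Note that the reported H/S of solutions 1 and 8 are not
consistent with their own frequency columns under the conversion formulas
(probable transcription errors); their frequency columns are still valid
anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .colorspace import SensorReading

__all__ = [
    "ReferenceSolution",
    "REFERENCE_SOLUTIONS",
    "DILUTION_ANCHORS",
    "JUICE_ANCHORS",
    "HEMOGLOBIN_WHOLE_BLOOD_MG_ML",
    "REPRODUCIBLE_ROWS",
]

#: Hemoglobin concentration of the donor whole blood, mg/ml (= g/L).
HEMOGLOBIN_WHOLE_BLOOD_MG_ML = 152.0


@dataclass(frozen=True)
class ReferenceSolution:
    """One measured solution: identity, channel frequencies, reported H/S."""

    number: int
    label: str
    dilution: float | None  # fold-dilution P for blood rows, None for juices
    f_red: float
    f_green: float
    f_blue: float
    reported_h: int
    reported_s: float

    def reading(self, t: float = 0.0, voltage: float = 3.0) -> SensorReading:
        return SensorReading(
            t=t, f_red=self.f_red, f_green=self.f_green, f_blue=self.f_blue,
            voltage=voltage,
        )


REFERENCE_SOLUTIONS: tuple[ReferenceSolution, ...] = (
    ReferenceSolution(1, "intestinal juice 1", None, 2.6483, 3.2657, 2.7727, 46, 0.33),
    ReferenceSolution(2, "intestinal juice 2", None, 3.0148, 3.9876, 4.4974, 60, 0.10),
    ReferenceSolution(3, "blood 512x", 512, 2.8477, 3.7075, 4.0711, 41, 0.20),
    ReferenceSolution(4, "blood 256x", 256, 2.7722, 3.5482, 3.8479, 35, 0.23),
    ReferenceSolution(5, "blood 128x", 128, 2.6774, 3.3041, 3.5226, 28, 0.27),
    ReferenceSolution(6, "blood 64x", 64, 2.5312, 2.8258, 2.9179, 20, 0.33),
    ReferenceSolution(7, "blood 32x", 32, 2.3521, 1.9657, 1.8391, 14, 0.42),
    ReferenceSolution(8, "blood 16x", 16, 2.1432, 1.2072, 1.4065, 9, 0.51),
    ReferenceSolution(9, "blood 4x", 4, 1.8243, 0.7237, 0.6862, 4, 0.60),
    ReferenceSolution(10, "blood undiluted", 1, 1.7325, 0.6087, 0.5918, 3, 0.63),
)

#: Rows whose reported H and S follow from their own frequencies (solutions
#: 1 and 8 do not; see module docstring).
REPRODUCIBLE_ROWS: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 9, 10)

#: Blood dilution anchors: fold-dilution P -> channel frequencies (kHz).
DILUTION_ANCHORS: dict[float, tuple[float, float, float]] = {
    sol.dilution: (sol.f_red, sol.f_green, sol.f_blue)
    for sol in REFERENCE_SOLUTIONS
    if sol.dilution is not None
}

#: Anchors consistent with the monotone dilution trend.  The 16-fold row's
#: frequencies place its derived hue on the wrong side of red (≈359°,
#: between 14° at 32-fold and 4° at 4-fold) with saturation below the
#: 32-fold row's — physically implausible for an intermediate dilution and
#: in line with that row's reported-H/S inconsistency — so it is dropped
#: from interpolation and its dilution is interpolated from its neighbors.
CONSISTENT_DILUTION_ANCHORS: dict[float, tuple[float, float, float]] = {
    p: f for p, f in DILUTION_ANCHORS.items() if p != 16
}

#: Simulated intestinal-juice baselines, keyed by short name.
JUICE_ANCHORS: dict[str, tuple[float, float, float]] = {
    "juice1": (2.6483, 3.2657, 2.7727),  # transparent yellow
    "juice2": (3.0148, 3.9876, 4.4974),  # colorless
}


def solution(number: int) -> ReferenceSolution:
    """Look up a reference solution by its 1-based number."""
    return REFERENCE_SOLUTIONS[number - 1]
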