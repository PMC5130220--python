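"""Duty-cycled capsule state machine, alarm telemetry, and power model.

After activation the capsule is dormant (default two hours, while it
transits the stomach behind its enteric coating).  It then alternates a
5 s sleep with a 0.5 s sampling window.  Each processed sample is
classified; a bleeding sample triggers an immediate alarm transmission
carrying its severity, and a sample taken below the capsule's voltage
threshold (2.4 V) with no bleeding triggers a single latched low-battery
alarm.  Alarms are one-byte codes rendered by the external receiver as
buzzer + 0-3 LEDs.

The power model is a duty-cycle average: the sensor (~2 mA), illumination
LEDs (~5 mA) and microcontroller (~0.6 mA) draw ~7.6 mA during the active
window and effectively nothing while sleeping, giving an average of about
0.7 mA (~2.1 mW at the 3.0 V regulated supply).  Transmission bursts are
treated as instantaneous and energetically free.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .classifier import (
    DEFAULT_SEVERITY_BANDS,
    DEFAULT_TARGET_AREA,
    Severity,
    SeverityBands,
    TargetArea,
    grade_severity,
)
from .colorspace import DEFAULT_WHITE_BALANCE, SensorReading, WhiteBalance, reading_to_hs
from .errors import ConfigError, ProtocolError, ReadingError

__all__ = [
    "CapsuleConfig",
    "AlarmKind",
    "AlarmMessage",
    "ReceiverState",
    "SampleEvent",
    "run_capsule",
    "encode_alarm",
    "decode_alarm",
    "active_current",
    "average_current",
    "average_power",
    "battery_life",
]


@dataclass(frozen=True)
class CapsuleConfig:
    """Timing and electrical parameters of the capsule.

    Defaults are the reference design's printed values.  Note the module
    voltage thresholds are not ordered around the capsule threshold: the
    detection module's own lower threshold (2.7 V) sits above the capsule
    threshold (2.4 V) because detection may still work somewhat below its
    nominal threshold, while the transmitter's (1.9 V) sits below it.
    Gating uses only ``v_capsule``; the other two are carried for
    documentation and assertions.
    """

    dormancy_s: float = 7200.0      # initial sleep after activation
    sleep_s: float = 5.0            # sleep window per duty cycle
    sample_s: float = 0.5           # active sampling window per duty cycle
    v_capsule: float = 2.4          # capsule lower voltage threshold (V)
    v_detect: float = 2.7           # detection-module lower threshold (V)
    v_transmit: float = 1.9         # transmitter lower threshold (V)
    supply_v: float = 3.0           # regulated supply voltage (V)
    i_sensor_ma: float = 2.0        # color sensor operating current
    i_led_ma: float = 5.0           # illumination circuit current
    i_mcu_ma: float = 0.6           # microcontroller operating current
    i_sleep_ma: float = 0.0         # dormant current (watchdog only)
    latch_low_battery: bool = True  # emit LOW_BATTERY at most once per run

    def __post_init__(self) -> None:
        if min(self.dormancy_s, self.sleep_s, self.sample_s) <= 0:
            raise ConfigError("all durations must be strictly positive")
        if min(self.i_sensor_ma, self.i_led_ma, self.i_mcu_ma, self.i_sleep_ma) < 0:
            raise ConfigError("currents must be non-negative")

    @property
    def period_s(self) -> float:
        """Duty-cycle period: one sleep window plus one sampling window."""
        return self.sleep_s + self.sample_s


class AlarmKind(enum.Enum):
    """The four capsule->receiver alarm messages."""

    BLEED_TRACE = "BLEED_TRACE"
    BLEED_SMALL = "BLEED_SMALL"
    BLEED_LARGE = "BLEED_LARGE"
    LOW_BATTERY = "LOW_BATTERY"


_SEVERITY_TO_ALARM = {
    Severity.TRACE: AlarmKind.BLEED_TRACE,
    Severity.SMALL: AlarmKind.BLEED_SMALL,
    Severity.LARGE: AlarmKind.BLEED_LARGE,
}

# One-byte wire codes; the low nibble of bleed codes is the LED count.
_ALARM_CODES = {
    AlarmKind.BLEED_TRACE: 0xB1,
    AlarmKind.BLEED_SMALL: 0xB2,
    AlarmKind.BLEED_LARGE: 0xB3,
    AlarmKind.LOW_BATTERY: 0xE0,
}
_CODE_TO_ALARM = {code: kind for kind, code in _ALARM_CODES.items()}


@dataclass(frozen=True)
class AlarmMessage:
    """One transmitted alarm: kind, emission time, one-byte payload."""

    kind: AlarmKind
    t: float
    payload: int

    @property
    def payload_hex(self) -> str:
        return f"0x{self.payload:02X}"


@dataclass(frozen=True)
class ReceiverState:
    """Rendering of a decoded alarm on the external receiver."""

    buzzer: bool
    leds_lit: int

    def __post_init__(self) -> None:
        if self.leds_lit > 0 and not self.buzzer:
            raise ProtocolError("LEDs may only light together with the buzzer")


@dataclass(frozen=True)
class SampleEvent:
    """Event-log record of one processed sample."""

    t: float
    h: float
    s: float
    voltage: float
    bleeding: bool
    severity: Severity
    alarm: AlarmKind | None


def encode_alarm(kind: AlarmKind) -> int:
    """Encode an alarm kind as its one-byte wire code."""
    return _ALARM_CODES[kind]


def decode_alarm(code: int) -> ReceiverState:
    """Decode a wire code into the receiver's buzzer/LED rendering.

    Trace/small/large bleeding light 1/2/3 LEDs with the buzzer; a
    low-battery alarm sounds the buzzer alone.
    """
    kind = _CODE_TO_ALARM.get(code)
    if kind is None:
        raise ProtocolError(f"unknown alarm code 0x{code:02X}")
    if kind is AlarmKind.LOW_BATTERY:
        return ReceiverState(buzzer=True, leds_lit=0)
    leds = {
        AlarmKind.BLEED_TRACE: 1,
        AlarmKind.BLEED_SMALL: 2,
        AlarmKind.BLEED_LARGE: 3,
    }[kind]
    return ReceiverState(buzzer=True, leds_lit=leds)


def run_capsule(
    stream: Sequence[SensorReading] | Iterable[SensorReading],
    cfg: CapsuleConfig = CapsuleConfig(),
    wb: WhiteBalance = DEFAULT_WHITE_BALANCE,
    area: TargetArea = DEFAULT_TARGET_AREA,
    bands: SeverityBands = DEFAULT_SEVERITY_BANDS,
) -> tuple[list[AlarmMessage], list[SampleEvent]]:
    """Run the capsule's work flow over a time-sorted reading stream.

    Readings before the dormancy period elapses, or arriving faster than
    the duty cycle allows, are skipped without processing.  Each processed
    sample with adequate voltage (``v >= v_capsule``) that classifies as
    bleeding emits one severity-graded alarm; a low-voltage sample with no
    bleeding emits a LOW_BATTERY alarm (once, if latching is enabled).  A
    bleeding sample at low voltage still emits its bleeding alarm —
    bleeding takes priority — and the voltage remains in the event log.

    Returns the transmitted alarms and the per-sample event log.
    """
    alarms: list[AlarmMessage] = []
    events: list[SampleEvent] = []
    next_due = cfg.dormancy_s
    low_battery_sent = False
    prev_t = float("-inf")

    for reading in stream:
        if reading.t < prev_t:
            raise ReadingError(
                f"stream not sorted by time: {reading.t} after {prev_t}"
            )
        prev_t = reading.t
        if reading.t < next_due:
            continue  # capsule asleep: reading falls outside a sampling window
        next_due = reading.t + cfg.period_s

        call = grade_severity(reading_to_hs(reading, wb), area, bands)
        alarm_kind: AlarmKind | None = None
        if call.bleeding:
            alarm_kind = _SEVERITY_TO_ALARM[call.severity]
        elif reading.voltage < cfg.v_capsule:
            if not (cfg.latch_low_battery and low_battery_sent):
                alarm_kind = AlarmKind.LOW_BATTERY
                low_battery_sent = True

        if alarm_kind is not None:
            alarms.append(
                AlarmMessage(kind=alarm_kind, t=reading.t, payload=encode_alarm(alarm_kind))
            )
        events.append(
            SampleEvent(
                t=reading.t,
                h=call.h,
                s=call.s,
                voltage=reading.voltage,
                bleeding=call.bleeding,
                severity=call.severity,
                alarm=alarm_kind,
            )
        )
    return alarms, events


def active_current(cfg: CapsuleConfig = CapsuleConfig()) -> float:
    """Total draw (mA) during the sampling window: sensor + LEDs + MCU."""
    return cfg.i_sensor_ma + cfg.i_led_ma + cfg.i_mcu_ma


def average_current(cfg: CapsuleConfig = CapsuleConfig()) -> float:
    """Duty-cycle-averaged current draw in mA."""
    active = active_current(cfg)
    return (active * cfg.sample_s + cfg.i_sleep_ma * cfg.sleep_s) / cfg.period_s


def average_power(cfg: CapsuleConfig = CapsuleConfig()) -> float:
    """Average power in mW at the regulated supply voltage."""
    return cfg.supply_v * average_current(cfg)


def battery_life(cfg: CapsuleConfig = CapsuleConfig(), capacity_mah: float = 40.0) -> float:
    """Runtime in hours on a battery of the given capacity (default 40 mAh)."""
    if capacity_mah < 0:
        raise ConfigError(f"battery capacity must be non-negative, got {capacity_mah}")
    return capacity_mah / average_current(cfg)
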