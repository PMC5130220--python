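"""Flat key-value run configuration.

A run config is a flat mapping of dotted keys to scalars, e.g.::

    # white balance (ms per channel)
    wb.t_red_ms = 81.4097
    region.h_high = 25
    severity.cuts = 8,15
    capsule.dormancy_s = 7200

Files are INI-style ``key = value`` lines (``#``/``;`` comments, blank lines
ignored, an optional ``[section]`` header is tolerated and ignored since
keys are already dotted).  Precedence is CLI override > file > defaults;
every override is recorded so provenance can be logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .capsule import CapsuleConfig
from .classifier import SeverityBands, TargetArea
from .colorspace import DEFAULT_WHITE_BALANCE, WhiteBalance
from .errors import ConfigError

__all__ = ["RunConfig", "DEFAULTS", "parse_config_file"]

DEFAULTS: dict[str, object] = {
    "wb.t_red_ms": DEFAULT_WHITE_BALANCE.t_red,
    "wb.t_green_ms": DEFAULT_WHITE_BALANCE.t_green,
    "wb.t_blue_ms": DEFAULT_WHITE_BALANCE.t_blue,
    "region.h_low": 3.0,
    "region.h_high": 25.0,
    "region.s_low": 0.3,
    "region.s_high": 0.8,
    "region.wraparound": False,
    "severity.cuts": (8.0, 15.0),
    "capsule.dormancy_s": 7200.0,
    "capsule.sleep_s": 5.0,
    "capsule.sample_s": 0.5,
    "capsule.v_capsule": 2.4,
    "capsule.v_detect": 2.7,
    "capsule.v_transmit": 1.9,
    "capsule.supply_v": 3.0,
    "capsule.i_sensor_ma": 2.0,
    "capsule.i_led_ma": 5.0,
    "capsule.i_mcu_ma": 0.6,
    "capsule.i_sleep_ma": 0.0,
    "capsule.latch_low_battery": True,
}


def _coerce(key: str, raw: str) -> object:
    """Coerce a raw string to the type of the key's default."""
    default = DEFAULTS[key]
    try:
        if isinstance(default, bool):
            low = raw.strip().lower()
            if low in ("1", "true", "yes", "on"):
                return True
            if low in ("0", "false", "no", "off"):
                return False
            raise ValueError(raw)
        if isinstance(default, tuple):
            parts = raw.strip().strip("[]() ").replace(";", ",").split(",")
            return tuple(float(p) for p in parts if p.strip())
        return float(raw)
    except ValueError as exc:
        raise ConfigError(f"cannot parse value {raw!r} for key {key!r}") from exc


def parse_config_file(path: str | Path) -> dict[str, object]:
    """Parse a flat key=value config file into typed overrides."""
    overrides: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", ";")):
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = stripped.partition("=")
        key = key.strip()
        if key not in DEFAULTS:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        overrides[key] = _coerce(key, value)
    return overrides


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration: defaults + file + CLI overrides."""

    values: dict[str, object] = field(default_factory=dict)
    overridden: tuple[str, ...] = ()

    @classmethod
    def load(
        cls,
        path: str | Path | None = None,
        cli_overrides: dict[str, object] | None = None,
    ) -> "RunConfig":
        merged = dict(DEFAULTS)
        overridden: dict[str, object] = {}
        if path is not None:
            file_vals = parse_config_file(path)
            merged.update(file_vals)
            overridden.update(file_vals)
        for key, val in (cli_overrides or {}).items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown config key {key!r}")
            coerced = _coerce(key, val) if isinstance(val, str) else val
            merged[key] = coerced
            overridden[key] = coerced
        return cls(values=merged, overridden=tuple(sorted(overridden)))

    def __getitem__(self, key: str) -> object:
        return self.values[key]

    def white_balance(self) -> WhiteBalance:
        return WhiteBalance(
            t_red=float(self.values["wb.t_red_ms"]),
            t_green=float(self.values["wb.t_green_ms"]),
            t_blue=float(self.values["wb.t_blue_ms"]),
        )

    def target_area(self) -> TargetArea:
        return TargetArea(
            h_low=float(self.values["region.h_low"]),
            h_high=float(self.values["region.h_high"]),
            s_low=float(self.values["region.s_low"]),
            s_high=float(self.values["region.s_high"]),
            wraparound=bool(self.values["region.wraparound"]),
        )

    def severity_bands(self) -> SeverityBands:
        cuts = self.values["severity.cuts"]
        return SeverityBands(cuts=tuple(float(c) for c in cuts))  # type: ignore[arg-type]

    def capsule(self) -> CapsuleConfig:
        v = self.values
        return CapsuleConfig(
            dormancy_s=float(v["capsule.dormancy_s"]),
            sleep_s=float(v["capsule.sleep_s"]),
            sample_s=float(v["capsule.sample_s"]),
            v_capsule=float(v["capsule.v_capsule"]),
            v_detect=float(v["capsule.v_detect"]),
            v_transmit=float(v["capsule.v_transmit"]),
            supply_v=float(v["capsule.supply_v"]),
            i_sensor_ma=float(v["capsule.i_sensor_ma"]),
            i_led_ma=float(v["capsule.i_led_ma"]),
            i_mcu_ma=float(v["capsule.i_mcu_ma"]),
            i_sleep_ma=float(v["capsule.i_sleep_ma"]),
            latch_low_battery=bool(v["capsule.latch_low_battery"]),
        )
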