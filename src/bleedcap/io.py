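"""CSV and raster I/O for readings, event logs, and image masks.

The readings dialect is fixed: comma-separated, ``.`` decimal point, header
``t_s,f_red_khz,f_green_khz,f_blue_khz,voltage_v``.  Writers emit the same
dialect they read so files round-trip losslessly at full precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .capsule import AlarmMessage, SampleEvent, decode_alarm
from .errors import FormatError

READINGS_COLUMNS = ["t_s", "f_red_khz", "f_green_khz", "f_blue_khz", "voltage_v"]
EVENT_COLUMNS = ["t_s", "kind", "payload_hex", "buzzer", "leds"]

__all__ = [
    "READINGS_COLUMNS",
    "read_readings_csv",
    "write_readings_csv",
    "write_event_log_csv",
    "read_raster",
    "write_pgm_mask",
]


def read_readings_csv(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read a readings CSV, enforcing the exact expected header."""
    try:
        frame = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=READINGS_COLUMNS)
    if list(frame.columns) != READINGS_COLUMNS:
        raise FormatError(
            f"bad readings header {list(frame.columns)}, expected {READINGS_COLUMNS}"
        )
    if not frame.empty and not frame[READINGS_COLUMNS].map(np.isreal).all().all():
        raise FormatError("readings must be numeric")
    return frame


def write_readings_csv(frame: pd.DataFrame, target: str | Path | IO[str]) -> None:
    frame.to_csv(target, index=False, columns=READINGS_COLUMNS)


def write_event_log_csv(alarms: list[AlarmMessage], target: str | Path | IO[str]) -> None:
    """Write transmitted alarms with their receiver rendering."""
    rows = []
    for a in alarms:
        state = decode_alarm(a.payload)
        rows.append((a.t, a.kind.value, a.payload_hex, int(state.buzzer), state.leds_lit))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(target, index=False)


def read_raster(path: str | Path) -> np.ndarray:
    """Load a PPM (P3/P6) or PNG image as an RGB array on the 0-255 scale."""
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"), dtype=float)
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot read raster {path}: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"empty raster {path}")
    return arr


def write_pgm_mask(mask: np.ndarray, target: str | Path) -> None:
    """Write a boolean mask as a plain-text PGM (P2), 0 outside / 255 inside."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise FormatError(f"mask must be 2-D, got shape {m.shape}")
    vals = np.where(m, 255, 0)
    lines = [f"P2", f"{m.shape[1]} {m.shape[0]}", "255"]
    lines += [" ".join(str(v) for v in row) for row in vals]
    Path(target).write_text("\n".join(lines) + "\n")
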