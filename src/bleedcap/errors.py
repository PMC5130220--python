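"""Exception hierarchy for bleedcap.

All package errors derive from :class:`BleedcapError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class BleedcapError(Exception):
    """Base class for all bleedcap errors."""


class CalibrationError(BleedcapError):
    """White-balance calibration is impossible or invalid."""


class ReadingError(BleedcapError):
    """A sensor reading violates its invariants."""


class ConfigError(BleedcapError):
    """A configuration value or file is malformed."""


class FormatError(BleedcapError):
    """An input file does not match the expected format."""


class ProtocolError(BleedcapError):
    """An alarm code cannot be decoded."""


class ScenarioError(BleedcapError):
    """A synthetic-scenario specification is inconsistent."""
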