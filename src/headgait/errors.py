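"""Exception hierarchy.

``ConfigError`` covers invalid parameters/configuration, ``DataError``
covers malformed or degenerate input data; the CLI maps the two branches
to distinct exit codes.
"""


class HeadgaitError(Exception):
    """Base class for all package errors."""


class ConfigError(HeadgaitError):
    """Invalid configuration or parameter value."""


class DataError(HeadgaitError):
    """Malformed or degenerate input data."""


class FormatError(DataError):
    """A time-series file violates the expected format."""


class SyncError(DataError):
    """Device synchronization from knock events is impossible."""


class CalibrationError(DataError):
    """Calibration segments are unusable (not static / ill-conditioned)."""
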