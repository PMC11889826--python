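"""Exception hierarchy shared by all pipeline stages."""


class CfmonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CfmonError):
    """A configuration value is invalid or inconsistent (exit code 2)."""


class DataFormatError(CfmonError):
    """An input file violates its expected format (exit code 3)."""


class InsufficientDataError(CfmonError):
    """Too few fragments/ends/values to compute a marker reliably."""


class CalibrationError(CfmonError):
    """Healthy reference cohort too small or degenerate for calibration."""
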