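"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`VoiceRiskError`
so callers can catch pipeline failures without masking programming errors.
"""


class VoiceRiskError(Exception):
    """Base class for all voicerisk errors."""


class ConfigurationError(VoiceRiskError, ValueError):
    """A configuration value is structurally invalid (e.g. non-positive dimension)."""


class ValidationError(VoiceRiskError, ValueError):
    """Data or a derived quantity violates a contract (e.g. non-PSD covariance)."""


class DegenerateDataError(VoiceRiskError, ValueError):
    """The input is too degenerate for the requested estimate (e.g. one speaker)."""


class CalibrationError(VoiceRiskError, RuntimeError):
    """Threshold calibration could not produce a usable threshold."""
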