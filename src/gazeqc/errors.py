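"""Exception and warning types shared across the package."""


class GazeQCError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazeQCError):
    """A data file does not conform to the validation-recording dialect."""


class ConfigError(GazeQCError):
    """A configuration value or file is invalid or missing."""


class DataQualityWarning(UserWarning):
    """Emitted when a metric cannot be computed and NaN is returned instead."""
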