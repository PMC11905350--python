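"""Exception hierarchy shared across the pipeline."""


class OptoEphysError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(OptoEphysError):
    """A configuration value is invalid; the message names the field."""


class ParameterError(OptoEphysError):
    """An analysis parameter is outside its valid range."""


class DataError(OptoEphysError):
    """Input data violate a precondition (too short, empty band, non-finite)."""


class AlignmentError(OptoEphysError):
    """Two series expected to share a time base do not."""


class NormalizationError(OptoEphysError):
    """Baseline normalization is numerically undefined for this input."""
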