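"""Exception hierarchy shared across the package."""


class SpikemodError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpikemodError, ValueError):
    """Invalid parameter combination in a config object."""


class ValidationError(SpikemodError, ValueError):
    """Data fails a structural precondition (bounds, alignment, pairing)."""


class SchedulingError(SpikemodError, ValueError):
    """Requested trials cannot be placed inside their window."""


class DegenerateDataError(SpikemodError, ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


class NormalizationError(SpikemodError, ValueError):
    """Spectral normalization against a zero or missing reference."""


class ParseError(SpikemodError, ValueError):
    """A session file is malformed; the message names the offending record."""
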