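"""Exception hierarchy for the ecochg package."""


class EcochgError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EcochgError, ValueError):
    """A model parameter violates its documented constraint."""


class ResolutionError(EcochgError, ValueError):
    """The sampling rate is too low to represent a requested waveform."""


class DegenerateInputError(EcochgError, ValueError):
    """An input signal carries no usable information (e.g. all zeros)."""


class InsufficientDataError(EcochgError, ValueError):
    """A recording is too short for the requested windowing."""


class ShapeError(EcochgError, ValueError):
    """Two series that must agree in shape or metadata do not."""


class ConfigurationError(EcochgError, ValueError):
    """Required analysis metadata is missing or inconsistent."""


class DataError(EcochgError, ValueError):
    """A data file could not be interpreted as a valid recording."""
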