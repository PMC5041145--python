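"""Exception types raised across the pipeline."""


class AllPhotonsError(Exception):
    """Base class for package errors."""


class GeometryError(AllPhotonsError):
    """A scene feature or grid request is geometrically invalid."""


class RegistrationError(AllPhotonsError):
    """Scene and measurement grids cannot be registered (non-integer
    pitch ratio or mismatched extents)."""


class NoSignalError(AllPhotonsError):
    """The measurement contains no frame above the noise floor."""


class InvalidProfileError(AllPhotonsError):
    """The temporal profile f_T is unusable (e.g. identically zero)."""


class InsufficientSignalError(AllPhotonsError):
    """Not enough usable frames/frame pairs for parameter estimation."""


class SizeCapError(AllPhotonsError):
    """An explicit dense operator would exceed the configured size cap."""


class StepSizeError(AllPhotonsError):
    """The iterative solver diverged; the step size exceeds 1/L."""


class FormatError(AllPhotonsError):
    """A file on disk does not match the expected container format."""


class ConfigError(AllPhotonsError):
    """A configuration mapping fails schema validation."""
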