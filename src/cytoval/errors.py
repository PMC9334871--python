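"""Exception hierarchy shared across the package."""


class CytovalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CytovalError):
    """A file does not conform to its declared format (FCS segment, CSV cell, ...)."""


class MappingError(CytovalError):
    """A channel name cannot be mapped to a role, or channel sets mismatch."""


class SpecError(CytovalError):
    """An invalid specification object (gate geometry, population fractions, ...)."""


class ConfigError(CytovalError):
    """An invalid or incomplete workflow/strategy configuration."""


class InsufficientDataError(CytovalError):
    """Too few events/pixels to compute the requested statistic."""


class DegenerateDataError(CytovalError):
    """Data admits no answer (constant image, zero isotype SD, ...)."""
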