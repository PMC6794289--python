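"""Exception hierarchy shared across the package."""


class PmrnaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PmrnaError, ValueError):
    """An input object or parameter violates a documented invariant."""


class LoadError(PmrnaError, ValueError):
    """A delimited-text input could not be read into a valid object."""


class DispersionError(PmrnaError, ValueError):
    """Replicate dispersion cannot be estimated from the given layout."""


class ContrastError(PmrnaError, ValueError):
    """A requested group contrast is absent from the sample sheet."""


class MarkerSelectionError(PmrnaError, ValueError):
    """Too few eligible genes to satisfy a marker-selection request."""


class PipelineError(PmrnaError, RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
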