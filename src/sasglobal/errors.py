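"""Exception hierarchy."""


class SasGlobalError(Exception):
    """Base class for all package errors."""


class CurveFormatError(SasGlobalError):
    """Malformed curve file (wrong column count, unreadable rows)."""


class MissingSigmaError(SasGlobalError):
    """Two-column curve file loaded without a sigma power-law k."""


class DataError(SasGlobalError):
    """Invalid data values (non-positive sigma, non-increasing q...)."""


class ParFileError(SasGlobalError):
    """Malformed parameter file."""


class LinkError(SasGlobalError):
    """Base class for link-expression errors."""


class LinkSyntaxError(LinkError):
    def __init__(self, message, position=None):
        self.position = position
        if position is not None:
            message = f"{message} (at offset {position})"
        super().__init__(message)


class LinkSemanticError(LinkError):
    pass


class LinkRuntimeError(LinkError):
    pass


class ParameterError(SasGlobalError):
    """Invalid model or distribution parameter value."""


class ConvergenceError(SasGlobalError):
    """A numerical solver failed to converge."""


class StabilityError(SasGlobalError):
    """Thermodynamically unstable input (e.g. RPA denominator <= 0)."""


class ConfigError(SasGlobalError):
    """Invalid run configuration."""
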