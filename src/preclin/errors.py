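"""Exception hierarchy shared across the pipeline stages."""


class PreclinError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PreclinError, ValueError):
    """A simulation or run configuration field violates its invariant."""


class InputError(PreclinError, ValueError):
    """Input data violate a structural precondition."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class StructuralError(InputError):
    """A dose grid is missing or duplicating required cells."""


class DegenerateControlError(InputError):
    """The control growth delta is zero, so relative growth is undefined."""


class InsufficientReplicatesError(InputError):
    """Fewer than two replicates per group; a t test cannot be formed."""


class ScalingUndefinedError(InputError):
    """All inhibitions are non-positive; heatmap scaling has no divisor."""
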