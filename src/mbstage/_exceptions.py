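"""Exception hierarchy shared across the package."""


class MbstageError(Exception):
    """Base class for all package errors."""


class FormatError(MbstageError):
    """A file does not conform to its declared dialect."""


class ValidationError(MbstageError):
    """Input data violate an invariant (duplicates, negative counts, ...)."""


class ParameterError(MbstageError):
    """A parameter is outside its documented domain."""


class GeometryError(MbstageError):
    """Spot geometry is degenerate (e.g. all spots coincident)."""


class DegenerateInputError(MbstageError):
    """A computation is undefined on this input (constant field, zero-variance PCA)."""


class DisconnectedLineageError(MbstageError):
    """Root and endpoint fall in different components of the pruned cluster graph."""

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = components or []
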