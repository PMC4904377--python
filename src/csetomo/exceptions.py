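"""Exception types shared across the package."""


class CsetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CsetError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(CsetError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (e.g. an all-zero image handed to a relative-threshold metric)."""


class NumericalFailureError(CsetError, ArithmeticError):
    """An iterative method produced a non-finite iterate."""


class FormatError(CsetError, IOError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(CsetError, ValueError):
    """Two inputs that must agree (e.g. stack size vs. angle count) do not."""
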