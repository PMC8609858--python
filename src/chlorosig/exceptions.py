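"""Exception hierarchy shared by all chlorosig modules."""


class ChlorosigError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ChlorosigError, ValueError):
    """An input violates a documented precondition or type invariant."""


class GeometryError(InvalidInputError):
    """Cell geometry is unphysical (overlapping cells, zero separation)."""


class UndefinedRatioError(ChlorosigError, ZeroDivisionError):
    """A ratio's denominator is zero (e.g. Fm = 0, Ddx + Dtx = 0)."""


class NumericalError(ChlorosigError, ArithmeticError):
    """A numerical routine failed to converge; message carries diagnostics."""
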