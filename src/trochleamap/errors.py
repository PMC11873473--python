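"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: input/validation problems exit 2,
numerical failures exit 3.
"""


class TrochleamapError(Exception):
    """Base class for all package errors."""


class FormatError(TrochleamapError):
    """A file could not be read or is not one of the supported formats."""


class ValidationError(TrochleamapError):
    """An input object violates a documented invariant."""


class GeometryError(TrochleamapError):
    """A geometric computation is degenerate (coincident points, etc.)."""


class NumericalError(TrochleamapError):
    """A numerical routine failed to converge or produced non-finite output."""
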