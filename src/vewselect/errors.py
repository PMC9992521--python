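"""Exception hierarchy for the selection pipeline.

Every stage raises a subclass of :class:`VewError` so callers can catch
pipeline failures without masking programming errors.
"""


class VewError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(VewError):
    """The input file or matrix is malformed (shape/label/ID problems)."""


class ParseError(VewError):
    """A cell could not be parsed as a number; carries row/column coordinates."""

    def __init__(self, message: str, row: int | None = None, column: int | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class DegenerateGeneError(VewError):
    """A gene has no observed values, so no mean can be imputed."""


class DegenerateTargetError(VewError):
    """The class labels contain a single class; supervised steps are undefined."""


class OrderingError(VewError):
    """Preprocessing steps were invoked in the wrong order (e.g. normalize before impute)."""


class EmptySelectionError(VewError):
    """A selection stage retained zero genes."""
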