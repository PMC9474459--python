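"""Exception hierarchy shared across the package."""


class TetramapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TetramapError):
    """Input values violate a documented invariant (negative area, bad sum...)."""


class EmptySampleError(ValidationError):
    """All compound peak areas are zero; no composition can be formed."""


class MissingStandardError(ValidationError):
    """Quantification requested without a usable internal standard."""


class SchemaError(TetramapError):
    """A table is missing required columns or has malformed cells."""


class OrderingError(TetramapError):
    """Depth or age values are not strictly increasing where required."""


class DegenerateWeightsError(TetramapError):
    """All susceptibility weights vanish inside a control interval."""


class ExtrapolationError(TetramapError):
    """A sample lies outside the span of the chronological control points."""


class InsufficientDataError(TetramapError):
    """Too few samples for the requested operation."""


class GridMismatchError(TetramapError):
    """Two series are not on the identical uniform age grid."""


class CollinearityError(TetramapError):
    """The regression design matrix is numerically singular."""


class DivergenceError(TetramapError):
    """Training produced a non-finite loss."""
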