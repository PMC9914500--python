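"""Exception hierarchy.

Every error the package raises derives from :class:`HoneySpecError`, so
callers can catch one base class at pipeline boundaries.
"""


class HoneySpecError(Exception):
    """Base class for all package errors."""


class GridError(HoneySpecError):
    """Wavenumber grid is malformed or does not match a model's grid."""


class DuplicateIdError(HoneySpecError):
    """Sample identifiers are not unique."""


class SpectraParseError(HoneySpecError):
    """A spectral or trait table cell could not be parsed."""


class EmptySelectionError(HoneySpecError):
    """A wavenumber region selection retained no grid points."""


class OutOfRangeError(HoneySpecError):
    """Resampling would extrapolate beyond the source grid."""


class ConfigError(HoneySpecError):
    """Invalid configuration."""


class MissingInputError(HoneySpecError):
    """A configured input file does not exist."""


class UnknownComponentError(HoneySpecError):
    """Requested component is not in the band library."""


class IncompleteTraitsError(HoneySpecError):
    """A trait row is missing fields required by the spectrum simulator."""


class TraitValidationError(HoneySpecError):
    """A trait value violates its physical bounds."""


class DegenerateTargetError(HoneySpecError):
    """Response variance is (numerically) zero; regression is undefined."""


class RankError(HoneySpecError):
    """More factors requested than the data can support."""


class SplitError(HoneySpecError):
    """Dataset too small to split."""


class InsufficientValidationError(HoneySpecError):
    """Too few validation samples for external validation statistics."""


class DomainError(HoneySpecError):
    """Argument outside the function's mathematical domain."""


class LabelError(HoneySpecError):
    """Unknown or missing class label."""


class DegenerateClassError(HoneySpecError):
    """Class models with zero self-residual; interclass distance undefined."""
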