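"""Exception hierarchy for the tractometry pipeline.

Every error raised on purpose by this package derives from
:class:`TractometryError`, so callers can catch one type at the CLI
boundary while tests can assert on the specific subclass.
"""


class TractometryError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TractometryError):
    """A file failed to parse under its declared dialect."""


class EmptyInputError(TractometryError):
    """A file or table parsed correctly but contains no usable records."""


class DimensionalityError(TractometryError):
    """A volume has the wrong number of dimensions for its declared kind."""


class SpecError(TractometryError):
    """A synthetic-data specification violates its own invariants."""


class ConfigError(TractometryError):
    """A run configuration value is out of range or inconsistent."""


class ManifestError(TractometryError):
    """A pipeline manifest references a participant or file that is unusable."""


class GeometryError(TractometryError):
    """A streamline is degenerate (zero length, too few points, non-finite)."""


class InsufficientBundleError(TractometryError):
    """Too few streamlines to estimate a core tract or profile."""


class InsufficientDataError(TractometryError):
    """Too few diffusion channels to fit the tensor model."""


class OutOfFieldOfViewError(TractometryError):
    """A node falls outside a scalar volume's field of view."""


class OrientationError(TractometryError):
    """A profile operation requires an orientation-tagged bundle."""


class DomainError(TractometryError):
    """A scalar argument is outside the mathematical domain of an operation."""


class CriterionError(TractometryError):
    """The blindsight criterion cannot be evaluated (missing 100% cell)."""


class ConvergenceError(TractometryError):
    """An iterative fit failed to converge or the input is degenerate."""


class DesignError(TractometryError):
    """A factorial design is unusable (empty cell, single-level factor)."""


class RegistrationError(TractometryError):
    """Two volumes do not share a grid and affine; resampling is out of scope."""


class UndefinedStatisticError(TractometryError):
    """A statistic is undefined on the given input (e.g. zero variance)."""
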