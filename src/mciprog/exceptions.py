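"""Exception hierarchy.

Everything derives from :class:`MciprogError` so callers can catch the
package's failures with a single except clause; most are also ``ValueError``
subclasses so that generic validation code behaves as expected.
"""


class MciprogError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(MciprogError, ValueError):
    """A required column is missing or has the wrong type."""


class CohortValidationError(MciprogError, ValueError):
    """A cohort invariant is violated (duplicate ids, inconsistent outcomes)."""


class ParseError(MciprogError, ValueError):
    """A cell could not be parsed as the required numeric type."""


class DegeneracyError(MciprogError, ValueError):
    """A quantity is degenerate (zero variance, zero matrix, coincident prototypes)."""


class DivergenceError(MciprogError, RuntimeError):
    """Training produced a non-finite cost."""


class ClassBalanceError(MciprogError, ValueError):
    """Labels do not contain both classes, or a class is too small."""


class SelectionError(MciprogError, ValueError):
    """Ensemble selection would retain zero members."""


class CalibrationError(MciprogError, RuntimeError):
    """Decline-rate boundary calibration failed (degenerate or non-monotone fit)."""


class AdjustmentError(MciprogError, ValueError):
    """Covariate adjustment could not be applied to a subject."""


class StratificationError(MciprogError, ValueError):
    """Cross-validation folds cannot be stratified with the given class sizes."""
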