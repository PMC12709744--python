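"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`PMStabilityError`, so callers can catch one type at the boundary.
"""


class PMStabilityError(Exception):
    """Base class for all package errors."""


class SchemaError(PMStabilityError):
    """A schema file or column-role mapping is malformed or inconsistent
    with the data file it describes."""


class ValidationError(PMStabilityError):
    """A cohort violates an invariant (missing cell, non-positive time,
    non-binary event indicator, ...). The message names the offending row."""


class DegeneratePredictorError(PMStabilityError):
    """A predictor cannot be standardised (zero standard deviation)."""


class AlignmentError(PMStabilityError):
    """A model and a cohort disagree about predictor columns."""


class StateError(PMStabilityError):
    """An operation was requested on a cohort lacking the required state
    (e.g. a follow-up summary without follow-up columns)."""


class CalibrationError(PMStabilityError):
    """The iterative (alpha, delta) search failed: the target C-index is
    unreachable on the bracket, or the iteration cap was exceeded."""


class SingularInformationError(PMStabilityError):
    """The unit information matrix is singular or numerically near-singular
    (condition number above the guard). Names the implicated columns."""


class FitError(PMStabilityError):
    """Maximum-likelihood estimation failed (no events, rank-deficient
    design, or non-convergence)."""
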