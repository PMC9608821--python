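"""Exception hierarchy.

All comprep-specific failures derive from :class:`ComprepError` so callers can
catch the package's errors with a single except clause while still receiving
standard ``ValueError`` semantics for bad inputs.
"""


class ComprepError(Exception):
    """Base class for all comprep errors."""


class DomainError(ComprepError, ValueError):
    """Input values outside the mathematical domain (negative proportions,
    zero-sum compositions, non-positive counts...)."""


class DimensionError(ComprepError, ValueError):
    """Mismatched vector lengths or component orderings."""


class SchemaError(ComprepError, ValueError):
    """Tables whose columns/labels do not line up (species lists, FA labels)."""


class ValidationError(ComprepError, ValueError):
    """File contents violating the panel invariants (row sums, duplicates)."""


class DegenerateDesignError(ComprepError, ValueError):
    """A factor with a single level, or otherwise unfittable layout."""


class DuplicateObservationError(ComprepError, ValueError):
    """Two observations occupy the same (predator, time) cell."""


class InsufficientReplicationError(ComprepError, ValueError):
    """Not enough residual degrees of freedom for the unbalanced estimator."""


class EstimationError(ComprepError, RuntimeError):
    """Diet-estimation optimizer failed to converge after restarts."""


class CalibrationError(ComprepError, RuntimeError):
    """Grid calibration could not reach the requested repeatability."""
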