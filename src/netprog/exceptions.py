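"""Exception hierarchy for netprog.

All errors raised by the package derive from :class:`NetprogError` so callers
can catch pipeline failures with a single ``except`` clause.
"""


class NetprogError(Exception):
    """Base class for all netprog errors."""


class InvalidConfigError(NetprogError):
    """A configuration object violates its invariants."""


class DomainError(NetprogError):
    """Input data violate a domain precondition (e.g. non-positive activity)."""


class CalibrationError(NetprogError):
    """Reference-group calibration is impossible (e.g. zero variance)."""


class LabelMismatchError(NetprogError):
    """Two region-labelled objects do not share the required label set."""


class InfeasibleEditError(NetprogError):
    """A planted covariance edit set cannot be realised as a valid covariance."""


class DegenerateDataError(NetprogError):
    """A statistic is undefined on the supplied data (zero variance, n too small)."""


class UndefinedMetricError(NetprogError):
    """A graph metric is undefined for the supplied graph (documented degenerate case)."""


class ConvergenceError(NetprogError):
    """An iterative model fit failed to converge."""
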