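"""Exception and warning hierarchy.

Every error raised by this package derives from :class:`MraqcError`, so
callers can catch the whole family with one clause.  Warnings derive from
:class:`MraqcWarning` and are emitted through the standard ``warnings``
machinery.
"""


class MraqcError(Exception):
    """Base class for all errors raised by mraqc."""


class ConfigurationError(MraqcError):
    """A config file or config mapping is malformed."""


class ValidationError(MraqcError):
    """Input data violates a domain invariant (unknown code, empty set, ...)."""


class IntegrityError(MraqcError):
    """Records contradict each other or the CRF dictionary."""


class SelectionError(MraqcError):
    """A random case selection was requested that cannot be satisfied."""


class StateError(MraqcError):
    """An operation was invoked from an illegal QC-state-machine phase."""


class AdjudicationError(MraqcError):
    """Discrepancy adjudication is missing, duplicated, or inconsistent."""


class EstimationError(MraqcError):
    """A statistical estimate is undefined or failed to converge."""


class MraqcWarning(UserWarning):
    """Base class for warnings emitted by mraqc."""


class DegenerateIntervalWarning(MraqcWarning):
    """A Wald interval collapsed to zero width (k = 0 or k = n)."""


class BoundaryEstimateWarning(MraqcWarning):
    """All clustered outcomes sit on the same boundary (all 0 or all n)."""
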