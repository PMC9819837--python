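"""Exception hierarchy.

All package-specific failures derive from :class:`CEAError` so callers can
catch one base class; validation failures additionally derive from
``ValueError`` where that is the natural Python idiom.
"""


class CEAError(Exception):
    """Base class for all markovcea errors."""


class InvalidCohortError(CEAError, ValueError):
    """Cohort counts are unusable (e.g. zero denominator, empty cohort)."""


class CountInconsistencyError(CEAError, ValueError):
    """Event counts contradict each other (e.g. more events than patients)."""


class InfiniteRateError(CEAError, ValueError):
    """A cumulative probability of 1 implies an infinite constant rate."""


class InvalidStrategyError(CEAError, ValueError):
    """Strategy inputs violate their invariants (probability sums, ranges)."""


class ConfigError(CEAError, ValueError):
    """An analysis configuration failed validation."""


class InfeasibleBetaError(CEAError, ValueError):
    """Requested mean/SD pair lies outside the Beta family's feasible set."""


class AmbiguousThresholdError(CEAError, RuntimeError):
    """A threshold search detected a non-monotone decision predicate."""


class MissingExposureError(CEAError, ValueError):
    """A health state has no observed person-time, so no mean is defined."""
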