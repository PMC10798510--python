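"""Named exception types raised by input validation and model evaluation."""


class AvrCeaError(Exception):
    """Base class for all package-specific errors."""


class MissingInputError(AvrCeaError):
    """A required file, key, or parameter row is absent."""


class MalformedValueError(AvrCeaError):
    """A value could not be parsed as the expected numeric type."""


class ValidationError(AvrCeaError):
    """A parsed value violates a domain invariant (e.g. probability > 1)."""


class InfeasibleMomentsError(AvrCeaError):
    """Requested (mean, se) cannot be matched by the target distribution."""


class LifeTableGapError(AvrCeaError):
    """The life table does not cover a required age."""


class MismatchedComparisonError(AvrCeaError):
    """Arm results being compared differ in stratum or perspective."""


class SingleArmCohortError(AvrCeaError):
    """Propensity matching requires both treated and control units."""
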