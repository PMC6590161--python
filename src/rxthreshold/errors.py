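"""Exception hierarchy for threshold-model computations."""


class ThresholdModelError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ThresholdModelError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InvalidScenarioError(DomainError):
    """A scenario's parameters produce terminal utilities outside [0, 1].

    Raised rather than clamping: silently clamping a negative utility would
    break the algebraic identity between the generic benefit/harm threshold
    and its evidence-based reformulation.
    """


class DoubleCountingError(ThresholdModelError):
    """The disease-probability threshold was requested for a scenario whose
    disease definition contains the outcome itself.

    In that regime the probability of disease and the utilities are not
    independent, so the classic threshold is not meaningful; the caller is
    directed to the outcome-risk threshold instead (disease taken as certain,
    P = 1).
    """


class KindMismatchError(ThresholdModelError, TypeError):
    """An estimate was compared against a threshold of the wrong kind
    (outcome risk vs disease probability)."""


class NoRootError(ThresholdModelError):
    """The expected-utility difference does not change sign over the
    requested bracket: the decision is uniform there and no indifference
    point exists."""
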