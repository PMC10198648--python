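"""Package-wide exception types."""


class HiddenSSEError(Exception):
    """Base class for package errors."""


class ParameterDomainError(HiddenSSEError, ValueError):
    """A rate or fraction lies outside its admissible domain."""


class ExtinctCladeError(HiddenSSEError):
    """A simulated clade lost all descendants of one (or both) crown lineages."""


class InfeasibleBandError(HiddenSSEError):
    """Rejection sampling cannot reach the requested tip-count band."""


class IneligibleTreeError(HiddenSSEError):
    """No sub-clade of the tree satisfies the biased-trimming eligibility rule."""


class InfeasibleTargetError(HiddenSSEError):
    """Heavy sub-clade trimming alone already overshoots the target fraction."""


class NumericalFailureError(HiddenSSEError):
    """The likelihood integrator failed or produced an invalid state."""


class FitFailureError(HiddenSSEError):
    """All likelihood evaluations in a fit were non-finite."""


class ConfigError(HiddenSSEError, ValueError):
    """An experiment configuration violates the study design."""
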