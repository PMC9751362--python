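"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration field is invalid."""


class SupportError(ValueError):
    """Response values lie outside the support of the assumed family."""


class IdentifiabilityError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


class DegenerateSampleError(ValueError):
    """A within-month sample has a zero pseudo-baseline denominator."""


class MonthRangeError(ValueError):
    """A requested month lies outside the simulated or observed range."""


class CompletenessError(ValueError):
    """Panel assembly found group-months with no observations."""


class EmptyPeriodError(ValueError):
    """A target-word distribution was requested for a period with no counts."""
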