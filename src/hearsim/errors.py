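"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input, configuration, or specification failed validation."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class UnsupportedRuleError(ValueError):
    """An adaptive-rule combination has no supported analytic solution."""
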