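"""Exception hierarchy shared across heritsim."""


class HeritsimError(Exception):
    """Base class for all heritsim errors."""


class ParameterError(HeritsimError, ValueError):
    """A simulation or estimator parameter is out of its valid range."""


class InvalidInputError(HeritsimError, ValueError):
    """An input value (empty list, unbalanced table, ...) is unusable."""


class InvalidStateError(HeritsimError, RuntimeError):
    """An operation was applied to an object in an impossible state."""


class DegenerateVarianceError(HeritsimError, ZeroDivisionError):
    """A heritability estimate is undefined because a variance is zero.

    Raised e.g. for parent-offspring regression on a population with no
    parental variance (sigma = sigma_env = 0) or ANOVA ratios on tables
    with no phenotypic variation at all.
    """
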