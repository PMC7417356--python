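"""Exception hierarchy shared across the package."""


class MarkovCEAError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MarkovCEAError, ValueError):
    """A numeric argument violates its stated domain (e.g. a non-positive Weibull scale)."""


class InsufficientDataError(MarkovCEAError, ValueError):
    """Too few usable observations to carry out an estimation step."""


class MalformedCurveError(MarkovCEAError, ValueError):
    """A digitized survival curve cannot be repaired into a valid survival function."""


class ConfigError(MarkovCEAError, ValueError):
    """A scenario configuration is missing, unknown, or violates an invariant.

    The message always names the offending key path.
    """
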