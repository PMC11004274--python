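"""Exception types shared across the pipeline stages."""


class PssaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PssaError):
    """A configuration value is missing, malformed, or inconsistent."""


class DataIntegrityError(PssaError):
    """An input table violates a structural constraint (e.g. an order dated
    outside its admission)."""


class ParameterError(PssaError):
    """A statistical routine received an out-of-domain argument."""


class UndefinedRatioError(PssaError):
    """A sequence ratio has a zero denominator and no continuity correction
    was requested."""


class DegenerateDistributionError(PssaError):
    """The index/marker day series carry no mass in any survey window."""
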