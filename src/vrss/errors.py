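"""Exception hierarchy shared across the package."""


class VrssError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VrssError, ValueError):
    """A numeric parameter is outside its documented domain."""


class ValidationError(VrssError, ValueError):
    """An instrument response violates its documented range or shape."""


class EmptySeriesError(VrssError, ValueError):
    """An operation received an ECG/RR series with no usable content."""


class UnusableEpochError(VrssError, ValueError):
    """An epoch has too few valid beats or spans too little time."""


class ZeroVarianceError(VrssError, ValueError):
    """A computation that requires dispersion received a constant input."""


class InfeasibleCorrelationError(VrssError, ValueError):
    """A requested correlation structure is not positive semi-definite."""


class ConfigError(VrssError, ValueError):
    """A run configuration file violates the schema."""
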