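"""Exception hierarchy.

Every failure mode the analysis surfaces maps onto one of these so callers
(and the CLI) can distinguish bad configuration from bad data from an
out-of-range request.
"""


class MemcurveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MemcurveError):
    """A model, scenario or run configuration is internally inconsistent."""


class ValidationError(MemcurveError):
    """Input data violate a documented invariant."""


class RangeError(MemcurveError):
    """A requested evaluation point lies outside the sampled range."""


class ExtrapolationError(RangeError):
    """Interpolation was requested outside the data; no silent extrapolation."""


class InsufficientDataError(ValidationError):
    """Fewer data points than the numerical stencil requires."""


class CenteringError(MemcurveError):
    """The midplane locator found no usable interior structure."""


class DegenerateProfileError(MemcurveError):
    """A profile is identically zero (or otherwise featureless)."""
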