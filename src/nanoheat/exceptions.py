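"""Exception hierarchy shared across the package.

Every stage of the pipelines raises a subclass of :class:`NanoheatError`
so callers (and the CLI) can tag failures with the stage that produced
them.
"""


class NanoheatError(Exception):
    """Base class for all package errors."""


class ValidationError(NanoheatError, ValueError):
    """Invalid input values or malformed configuration."""


class RangeError(NanoheatError, ValueError):
    """A query outside the tabulated/valid domain (e.g. wavelength)."""


class GeometryError(NanoheatError, ValueError):
    """Inconsistent particle geometry (e.g. core radius >= outer radius)."""


class ConvergenceError(NanoheatError, ArithmeticError):
    """A series did not converge to the requested tolerance."""


class DetectionError(NanoheatError, RuntimeError):
    """No particle could be located in an image."""


class FootprintError(NanoheatError, RuntimeError):
    """The melted footprint could not be measured (e.g. exceeds the field)."""


class EnvironmentError_(NanoheatError, ValueError):
    """Thermal-environment constants are inconsistent (e.g. T_m <= T_ambient)."""


class FitError(NanoheatError, RuntimeError):
    """A regression could not be performed (e.g. all points saturated)."""
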