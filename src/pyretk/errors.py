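"""Exception hierarchy.

Everything raised on purpose by pyretk derives from :class:`PyretkError`
so callers can catch the package's own failures without swallowing
programming errors.
"""


class PyretkError(Exception):
    """Base class for all pyretk errors."""


class ParameterError(PyretkError, ValueError):
    """A rate constant or fraction is missing, non-positive or out of range."""


class ConstraintError(ParameterError):
    """A physiological ordering constraint between isomers is violated.

    The message names the violated constraint, e.g.
    ``trans.k_abs_oral >= cis.k_abs_oral``.
    """


class UnsupportedRouteError(PyretkError, ValueError):
    """A scenario uses a route whose absorption rate is not parameterised."""


class IntegrationError(PyretkError, RuntimeError):
    """The ODE solver failed or produced an unacceptably negative state."""


class AsymptoteNotReachedError(PyretkError, RuntimeError):
    """Cumulative urinary excretion has not plateaued over the simulated span."""


class InsufficientDataError(PyretkError, ValueError):
    """Too few usable observations inside a fitting window."""


class WindowError(PyretkError, ValueError):
    """A fitting window does not intersect the observed voids."""


class UnidentifiableError(PyretkError, ValueError):
    """The requested fit has a degenerate (flat or all-zero) objective."""


class TimecourseParseError(PyretkError, ValueError):
    """An observed time-course file violates the documented CSV dialect."""
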