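"""Exception hierarchy.

All package errors derive from :class:`NgbKinError` so callers can catch one
type; the concrete classes also subclass the matching builtin so that generic
``except ValueError`` style handling keeps working.
"""


class NgbKinError(Exception):
    """Base class for all errors raised by ngbkin."""


class DomainError(NgbKinError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class ConfigurationError(NgbKinError, ValueError):
    """A configuration object is inconsistent (unknown labels, bad wiring)."""


class FitError(NgbKinError, RuntimeError):
    """A least-squares fit failed or produced a rejected solution."""


class IntegrationError(NgbKinError, RuntimeError):
    """The ODE integrator failed to converge."""
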