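"""Exception hierarchy for pvshell.

All errors raised by the library derive from :class:`PVShellError` so that
callers (and the CLI) can distinguish domain problems from programming
errors.
"""


class PVShellError(Exception):
    """Base class for all pvshell errors."""


class DomainError(PVShellError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class QuadratureError(PVShellError, ArithmeticError):
    """The pressure integral failed to converge to the requested tolerance."""


class BracketingError(PVShellError, ValueError):
    """A root bracket does not contain a sign change."""


class ConfigurationError(PVShellError, ValueError):
    """A model or run configuration is incomplete or inconsistent."""


class PhysiologyError(PVShellError, ValueError):
    """A result is physiologically inconsistent (e.g. ESV >= EDV)."""


class FittingError(PVShellError, RuntimeError):
    """All optimizer starts failed to converge."""


class ParseError(PVShellError, ValueError):
    """A dataset file could not be parsed."""
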