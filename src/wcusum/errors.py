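"""Typed exceptions used across the package.

The hierarchy separates user-input problems (bad shapes, bad parameters)
from data pathologies (constant series, zero count rows) and numerical
failures (quadrature non-convergence), so callers and the CLI can map
them to distinct exit codes.
"""


class WCUSUMError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(WCUSUMError, ValueError):
    """A parameter or input array violates a precondition."""


class UnsupportedOperationError(WCUSUMError, ValueError):
    """The requested operation is not defined for these parameters."""


class DegenerateDataError(WCUSUMError, ValueError):
    """The data admit no meaningful statistic (e.g. a constant series)."""


class NumericalError(WCUSUMError, RuntimeError):
    """A numerical routine failed to reach its target accuracy."""
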