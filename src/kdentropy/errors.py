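"""Exception hierarchy.

All rejected inputs raise :class:`DataError` (a ``ValueError``) so callers can
distinguish bad data from programming errors; the CLI maps it to exit code 1.
"""


class KdentropyError(Exception):
    """Base class for all package errors."""


class DataError(KdentropyError, ValueError):
    """Invalid or degenerate input data."""


class ConvergenceError(KdentropyError, RuntimeError):
    """A numerical routine failed to converge where a result is mandatory."""
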