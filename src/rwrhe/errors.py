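"""Typed exceptions raised by the rwrhe pipeline.

Every reader and numerical operation fails with one of these instead of a
bare ``ValueError`` so that callers (and the CLI) can distinguish malformed
input from degenerate data from numerical failure.
"""


class RwrheError(Exception):
    """Base class for all package errors."""


class FormatError(RwrheError):
    """An on-disk artifact does not conform to its documented dialect."""


class EmptyInputError(RwrheError):
    """An input that must contain data is empty."""


class OutOfRangeError(RwrheError):
    """A value lies outside its documented range (e.g. unscaled edge scores)."""


class AlignmentError(RwrheError):
    """Two labelled objects do not share a compatible index."""


class DegenerateInputError(RwrheError):
    """Input is syntactically valid but numerically unusable (e.g. all-zero)."""


class ConvergenceError(RwrheError):
    """An iterative solver failed to reach tolerance within max_iterations."""

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual
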