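"""Exception hierarchy shared across the toolkit.

Operations distinguish three failure modes: inputs that violate a
documented precondition (:class:`DegenerateDataError`), optimizers that do
not converge (:class:`FitConvergenceError`, which carries the best
candidate found), and signals in which a sought feature is absent
(:class:`NoCrossingError`).
"""

from __future__ import annotations


class FoldkitError(Exception):
    """Base class for all toolkit errors."""


class DegenerateDataError(FoldkitError, ValueError):
    """Input violates a precondition (too few points, constant signal, ...)."""


class FitConvergenceError(FoldkitError):
    """An optimizer failed to converge.

    The best candidate found across all starts (if any) is attached as
    ``best`` so callers can inspect how far the fit got.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class NoCrossingError(FoldkitError):
    """The signal never reaches the sought level (e.g. no folding detected)."""


class ParseError(FoldkitError, ValueError):
    """A file could not be parsed; carries the offending line/row number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
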