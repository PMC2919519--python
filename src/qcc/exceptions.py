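"""Typed errors raised across the package.

Undefined correlations (zero-variance inputs) surface as
:class:`UndefinedCorrelationError`, never as a silent NaN.
"""


class QCCError(Exception):
    """Base class for all package errors."""


class ParameterError(QCCError, ValueError):
    """An argument is outside its documented range."""


class DataError(QCCError, ValueError):
    """Input data violate a structural requirement (empty, malformed, unmatched)."""


class ParseError(DataError):
    """A track file could not be parsed; the message carries the line number."""


class UndefinedCorrelationError(QCCError, ArithmeticError):
    """A correlation is undefined because one input has zero variance."""
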