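"""Exception hierarchy shared across the package.

Precondition violations raise :class:`InvalidArgumentError` (a ``ValueError``),
so callers that do not care about the distinction can catch ``ValueError``.
Analysis-stage failures get their own classes because the CLI maps them to
distinct exit codes.
"""


class TranslokinError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(TranslokinError, ValueError):
    """A precondition on an argument was violated."""


class OutOfRangeError(InvalidArgumentError):
    """A query time or coordinate lies outside the valid domain."""


class DegenerateFitError(TranslokinError):
    """The data carry no signal the estimator can use (e.g. an all-zero trace)."""


class InsufficientDataError(TranslokinError):
    """Too few usable points remain after exclusions to fit the model."""


class ConvergenceError(TranslokinError):
    """The nonlinear optimiser failed to converge within its iteration budget."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedStatisticError(TranslokinError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class MissingDataError(TranslokinError):
    """Requested time points are absent from one or more traces."""

    def __init__(self, message: str, offenders: list | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class ParseError(TranslokinError):
    """An input file violates the expected schema."""


class LayoutOverflowError(TranslokinError):
    """More cells were requested than the image layout can hold."""
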