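"""Exception hierarchy for bilicomp.

All package-specific errors derive from :class:`BilicompError` so callers can
catch everything with one clause; the finer-grained classes distinguish bad
inputs (``DomainError``), failed or degenerate model fits (``FitError`` and
subclasses), and malformed files (``ParseError``).
"""


class BilicompError(Exception):
    """Base class for all bilicomp errors."""


class DomainError(BilicompError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class ParameterizationError(BilicompError, ValueError):
    """A parameter combination produces a non-physical model output."""


class FitError(BilicompError, RuntimeError):
    """A model fit failed or its preconditions were not met."""

    def __init__(self, message: str, initial_params=None):
        super().__init__(message)
        self.initial_params = initial_params


class DegenerateFitError(FitError):
    """The fit is degenerate (e.g. no spread in the predictor)."""


class MissingReferenceError(BilicompError, KeyError):
    """A bilirubin level has no non-hemolyzed reference measurement."""


class InvalidCorrectionError(BilicompError, ValueError):
    """The hemoglobin correction produced a non-positive reflectance."""


class ParseError(BilicompError, ValueError):
    """A measurement/estimate/config file is malformed."""
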