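"""Exception hierarchy for movefda.

All package-specific errors derive from :class:`MoveFdaError` so callers can
catch everything from one place while the pipeline reports the failing stage.
"""


class MoveFdaError(Exception):
    """Base class for all movefda errors."""


class ConfigurationError(MoveFdaError):
    """Invalid configuration, e.g. a required CSV column is missing."""


class EmptyInputError(MoveFdaError):
    """An operation received no usable rows/records."""


class ParameterError(MoveFdaError):
    """A numeric parameter is outside its valid range."""


class DomainError(MoveFdaError):
    """Evaluation requested outside a model's fitted time domain."""


class DegenerateKnotsError(MoveFdaError):
    """Knot selection produced no usable interior knots."""


class FitError(MoveFdaError):
    """The penalized least-squares system could not be solved."""


class TuningError(MoveFdaError):
    """No candidate smoothing penalty produced a defined GCV score."""


class NoOverlapError(MoveFdaError):
    """Two animals' monitoring domains share fewer than two grid points."""


class WindowError(MoveFdaError):
    """A summary window does not intersect the series' time grid."""
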