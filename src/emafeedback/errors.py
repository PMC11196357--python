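"""Error hierarchy for the EMA feedback pipeline.

Every error raised on purpose by this package derives from
:class:`EMAError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class EMAError(Exception):
    """Base class for all errors raised by this package."""


class CodebookError(EMAError):
    """A variable codebook violates its invariants."""


class MissingColumnError(EMAError):
    """A required column is absent from an input table."""


class EmptyTableError(EMAError):
    """An input table contains no usable records."""


class ParameterError(EMAError):
    """A numeric or configuration parameter is out of range."""


class InsufficientDataError(EMAError):
    """Too few observations for the requested analysis."""


class EstimationError(EMAError):
    """A model fit failed (singular covariance, non-convergence)."""
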