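"""Exception hierarchy.

Every error raised by this package derives from :class:`DrugClfError`, so callers
can catch one base class at a pipeline boundary while tests can assert on the
specific failure mode.
"""


class DrugClfError(Exception):
    """Base class for all drugclf errors."""


class SchemaError(DrugClfError, ValueError):
    """Matrix/feature/sample identifiers are inconsistent or malformed."""


class DataQualityError(DrugClfError, ValueError):
    """Non-finite or otherwise unusable values in the data."""


class InvalidResponseError(DrugClfError, ValueError):
    """Response vector incompatible with the requested GLM family."""


class EmptyInputError(DrugClfError, ValueError):
    """Zero rows, zero features, or too few samples to do anything."""


class ConfigurationError(DrugClfError, ValueError):
    """Infeasible or invalid parameters (fold counts, gene counts, configs)."""


class StratificationError(ConfigurationError):
    """A class is absent from a fold or split where it is required."""


class StateError(DrugClfError, RuntimeError):
    """Operation requires state (a fitted model, p-values) that is missing."""


class UndefinedROCError(DrugClfError, ValueError):
    """ROC/AUC requested but only one class is present."""


class UndefinedR2Error(DrugClfError, ValueError):
    """R^2 requested for a zero-variance response."""


class SampleSizeError(DrugClfError, ValueError):
    """Too few usable samples (e.g. cell lines with measured sensitivity)."""


class DrugLookupError(DrugClfError, KeyError):
    """Unknown drug identifier, or no fitted model for it."""


class InterpolationError(DrugClfError, ValueError):
    """Scattered-data interpolation is impossible (e.g. collinear points)."""


class ParseError(DrugClfError, ValueError):
    """A delimited text file could not be parsed; message carries location."""
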