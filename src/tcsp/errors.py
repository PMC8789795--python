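"""Exception hierarchy.

All domain errors derive from :class:`TcspError` so CLI code can map them
to a nonzero exit with a structured message.
"""


class TcspError(Exception):
    """Base class for all tcsp domain errors."""


class InputFormatError(TcspError):
    """A table or file could not be parsed into a valid domain object."""


class DegenerateSampleError(TcspError):
    """A sample is unusable (e.g. an all-zero count column)."""


class ModelFormatError(TcspError):
    """A signature-model file is malformed or missing required columns."""


class UnsupportedVersionError(ModelFormatError):
    """A signature-model file declares a version this build cannot read."""


class ParameterError(TcspError):
    """A parameter is outside its documented domain."""


class LabelingError(TcspError):
    """Reference labels are inconsistent with the expression matrix."""


class ConstructionError(TcspError):
    """A signature model could not be built (e.g. empty gene union)."""


class CoverageError(TcspError):
    """Too few model genes were found in a query sample."""


class UndefinedNormalizationError(TcspError):
    """Sum-normalization requested for an estimate whose total is zero."""


class UndefinedRatioError(TcspError):
    """Composite ratio with a zero denominator; carries both operands."""

    def __init__(self, numerator_value: float, denominator_value: float, message: str | None = None):
        self.numerator_value = numerator_value
        self.denominator_value = denominator_value
        super().__init__(
            message
            or f"undefined ratio: numerator={numerator_value!r}, denominator={denominator_value!r}"
        )


class ConfigError(TcspError):
    """A synthesis or run configuration is invalid."""
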