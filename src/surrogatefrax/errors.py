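"""Exception hierarchy shared across the package."""


class SurrogateFraxError(Exception):
    """Base class for all package errors."""


class SchemaError(SurrogateFraxError):
    """A file does not match the expected CSV schema."""


class ValidationError(SurrogateFraxError):
    """A table or profile violates an invariant (negative rate, band gap...)."""


class AgeRangeError(SurrogateFraxError):
    """A requested age or year lies outside table coverage."""


class AlignmentError(SurrogateFraxError):
    """Two tables that must share band structure do not."""


class InsufficientDataError(SurrogateFraxError):
    """Too few data points for the requested statistic."""


class DegenerateDataError(SurrogateFraxError):
    """Data without the variation the statistic requires."""


class ConfigurationError(SurrogateFraxError):
    """Invalid run configuration or unknown risk-factor name."""


class EmptySelectionError(SurrogateFraxError):
    """A filter matched no rows."""
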