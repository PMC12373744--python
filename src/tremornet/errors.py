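"""Exception hierarchy shared across the package."""


class TremornetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TremornetError):
    """A file could not be parsed; the message names the offending content."""


class AlignmentError(TremornetError):
    """Subject ids (or orderings) of two inputs do not coincide."""


class ValidationError(TremornetError):
    """A domain-type invariant was violated."""


class NamingError(TremornetError):
    """A region/structure/ROI name does not exist or is duplicated."""


class ConfigurationError(TremornetError):
    """A parameter value is outside its admissible range."""


class DesignError(TremornetError):
    """A design matrix is rank deficient or misaligned."""


class DegenerateDataError(TremornetError):
    """A regressor or field is constant where variation is required."""


class UsageError(TremornetError):
    """An operation was applied to inputs it is not defined for."""


class EvaluationError(TremornetError):
    """Model evaluation could not produce a valid result."""
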