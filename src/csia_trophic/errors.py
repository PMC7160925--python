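"""Exception hierarchy shared across the package."""


class CSIATrophicError(Exception):
    """Base class for all package errors."""


class ParseError(CSIATrophicError):
    """A cell could not be parsed; the message names the row and column."""


class VocabularyError(CSIATrophicError):
    """A tissue, period or amino-acid token is outside the controlled vocabulary."""


class ValidationError(CSIATrophicError):
    """A value violates a type invariant (non-finite, out of range, ...)."""


class MissingAminoAcidError(CSIATrophicError):
    """An estimator was invoked on a profile lacking a required amino acid."""


class ConfigurationError(CSIATrophicError):
    """A TDF configuration entry required by the operation is absent or invalid."""


class InsufficientDataError(CSIATrophicError):
    """A statistical test was invoked with fewer observations than it requires."""


class DegenerateVarianceError(CSIATrophicError):
    """A test statistic is undefined because the sample variance is zero."""
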