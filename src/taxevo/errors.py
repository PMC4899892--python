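"""Exception hierarchy shared across the pipeline.

Every error raised on purpose by this package derives from :class:`TaxevoError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class TaxevoError(Exception):
    """Base class for all errors raised by taxevo."""


class ValidationError(TaxevoError):
    """An input value violates a documented invariant (names the field)."""


class ConfigurationError(TaxevoError):
    """Inputs are individually valid but mutually inconsistent with the run
    configuration (e.g. VCF samples do not match the stage series)."""


class ParseError(TaxevoError):
    """A file is malformed; the message carries the offending line/record."""


class VocabularyError(TaxevoError):
    """A consequence term (or hallmark category) outside the closed vocabulary."""


class ConsistencyError(TaxevoError):
    """Cross-file disagreement, e.g. region definitions differ between stages."""


class EstimationError(TaxevoError):
    """Too little data to estimate a null distribution."""


class NonGrowingCurveError(TaxevoError):
    """Growth-rate fit returned k <= 0; doubling time undefined."""


class UndefinedRatioError(TaxevoError):
    """Survival ratio with zero parental viability."""
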