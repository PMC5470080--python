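"""Exception hierarchy shared across the package."""


class BsrseqError(Exception):
    """Base class for all bsrseq errors."""


class FormatError(BsrseqError, ValueError):
    """A file or record violates its declared format."""


class DuplicateRecordError(FormatError):
    """Two records share a key that must be unique."""


class ConfigError(BsrseqError, ValueError):
    """A configuration object violates its invariants."""


class DomainError(BsrseqError, ValueError):
    """A numeric argument lies outside the mathematically valid domain."""


class UndefinedSiteError(BsrseqError, ValueError):
    """A site carries no reads, so the requested statistic is undefined."""


class UndefinedResultError(BsrseqError, ValueError):
    """The requested posterior is undefined for the given counts."""


class EstimationError(BsrseqError, RuntimeError):
    """An empirical-Bayes estimate cannot be computed from the given data."""


class ConsistencyError(BsrseqError, ValueError):
    """An internal table violates an invariant it should carry by construction."""


class StageError(BsrseqError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
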