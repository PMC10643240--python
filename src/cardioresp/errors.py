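"""Exception hierarchy shared across the package."""


class CardiorespError(Exception):
    """Base class for all package errors."""


class ValidationError(CardiorespError):
    """A domain invariant was violated."""


class LoadError(CardiorespError):
    """A record could not be read (missing channel, malformed file)."""


class ConfigurationError(CardiorespError):
    """Inconsistent or unsupported configuration."""


class AnalysisError(CardiorespError):
    """Input does not support the requested analysis (too short, degenerate)."""


class ExcludedRecordError(CardiorespError):
    """Structured refusal: the record fails the exclusion gate.

    Carries the machine-readable reason so callers can report it instead of
    treating the refusal as a crash.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
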