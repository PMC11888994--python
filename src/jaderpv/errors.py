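"""Exception types shared across the package."""


class JaderpvError(Exception):
    """Base class for all package errors."""


class TableFormatError(JaderpvError):
    """A source table is malformed (e.g. a mandatory column is missing)."""


class IntegrityError(JaderpvError):
    """Relational integrity violated (e.g. duplicate DEMO case id)."""


class ConfigurationError(JaderpvError):
    """Invalid configuration (empty SMQ, bad probability vector, ...)."""


class DomainError(JaderpvError, ValueError):
    """An argument is outside the operation's domain."""


class DegenerateSampleError(JaderpvError):
    """A sample admits no proper fit (e.g. all onset days identical)."""


class DegenerateRuleError(JaderpvError):
    """A rule's contingency makes the chi-squared statistic undefined."""


class PipelineStageError(JaderpvError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
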