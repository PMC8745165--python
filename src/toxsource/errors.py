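"""Exception hierarchy shared across the package."""


class ToxSourceError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ToxSourceError):
    """A table file is missing, or its header does not match the schema."""


class ValidationError(ToxSourceError):
    """A record violates a domain invariant (bad EC, dangling key, ...)."""


class StageError(ToxSourceError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
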