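"""Exception hierarchy.

All errors raised by this package derive from :class:`FermentomeError` so
callers can catch one base class at pipeline boundaries.
"""


class FermentomeError(Exception):
    """Base class for all package errors."""


class SchemaError(FermentomeError):
    """A table file does not match the expected column schema."""


class ParseError(FermentomeError):
    """A cell could not be parsed into its declared type."""


class ValidationError(FermentomeError):
    """A table or record violates a domain invariant."""


class ConfigurationError(FermentomeError):
    """Thresholds, pathway maps or quotas are internally inconsistent."""


class DesignError(FermentomeError):
    """A community cannot be assembled under the requested quotas."""


class FitError(FermentomeError):
    """A model fit failed to converge."""


class StageError(FermentomeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
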