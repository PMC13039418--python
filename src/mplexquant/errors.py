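"""Exception hierarchy shared across the pipeline stages."""


class MplexError(Exception):
    """Base class for all package errors."""


class FormatError(MplexError, ValueError):
    """A file's on-disk layout does not match the expected schema."""


class ValidationError(MplexError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(MplexError, ValueError):
    """A configuration entry is unknown or inconsistent."""


class CapacityError(MplexError, RuntimeError):
    """A randomized placement could not be satisfied within bounded retries."""


class EstimationError(MplexError, RuntimeError):
    """An estimator received degenerate input (e.g. a constant image)."""


class ConsistencyError(MplexError, ValueError):
    """Two inputs that must agree (label maps, shapes) do not."""


class StageError(MplexError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
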