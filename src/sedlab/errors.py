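"""Exception hierarchy shared across sedlab."""


class SedlabError(Exception):
    """Base class for all sedlab errors."""


class DomainError(SedlabError, ValueError):
    """An input value is outside the physical/mathematical domain of an operation."""


class InputError(SedlabError, ValueError):
    """A structurally invalid input (wrong shape, too few points, empty)."""


class SchemaError(SedlabError, ValueError):
    """A table does not conform to the expected column schema."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class FitError(SedlabError, RuntimeError):
    """A model fit failed (rank deficiency, non-convergence)."""


class EstimationError(SedlabError, RuntimeError):
    """An estimator cannot produce a meaningful value (e.g. non-positive growth)."""


class StateError(SedlabError, RuntimeError):
    """An object was used before being fitted/configured."""


class ConfigError(SedlabError, ValueError):
    """Invalid pipeline or generator configuration."""


class StageError(SedlabError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
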