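"""Exception hierarchy shared across the package."""


class DpikitError(Exception):
    """Base class for all package errors."""


class InputError(DpikitError, ValueError):
    """Malformed or missing input data."""


class NonPhysicalAngleError(DpikitError, ValueError):
    """Contact-angle set admits no positive surface-energy root."""


class DegenerateInputError(DpikitError, ValueError):
    """Inputs collapse the computation (e.g. both dispersive parts zero)."""


class DegenerateDistributionError(DpikitError, ValueError):
    """Too few usable points to regress a size distribution."""


class PipelineStageError(DpikitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
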