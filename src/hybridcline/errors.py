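"""Exception and warning types shared across the package."""


class SchemaError(ValueError):
    """An input table is missing required columns or violates the schema."""


class CoordinateError(ValueError):
    """A coordinate or region lies outside its legal range."""


class DegenerateGeometryError(ValueError):
    """Specimen coordinates do not define a usable transect line."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested analysis."""


class NonClinalDataError(ValueError):
    """The response shows no variation, so a cline cannot be fitted."""


class UnstableBootstrapWarning(UserWarning):
    """Fewer retained bootstrap replicates than is safe for interval estimates."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
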