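"""Exception hierarchy shared across the pipeline."""


class NicheQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NicheQuantError):
    """An input table/file does not match the expected schema."""


class EmptyTissueError(NicheQuantError):
    """A tissue has no usable (DAPI-positive) cells."""


class GeometryError(NicheQuantError):
    """Masks, frames, or polygons are invalid or inconsistent."""


class UndefinedDistanceError(NicheQuantError):
    """Nearest-neighbor distance requested against an empty target set."""


class DegenerateTestError(NicheQuantError):
    """A statistical test has no information (e.g. all paired differences zero)."""


class UndefinedCorrelationError(NicheQuantError):
    """Correlation requested on constant input."""


class InvalidMeasurementError(NicheQuantError):
    """A clinical measurement violates its preconditions (e.g. baseline <= 0)."""


class IncompleteSeriesError(NicheQuantError):
    """A lesion series is missing its baseline measurement."""


class DataError(NicheQuantError):
    """A record is malformed (bad grade, bad VAF, ...)."""


class ValidationFailure(NicheQuantError):
    """Fatal input-validation problems; maps to CLI exit code 2."""


class StageError(NicheQuantError):
    """A pipeline stage failed; maps to CLI exit code 3."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
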