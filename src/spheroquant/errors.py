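"""Exception hierarchy for spheroquant.

Every error raised by the package derives from :class:`SpheroquantError`,
so callers (and the CLI) can catch package failures with a single clause.
"""


class SpheroquantError(Exception):
    """Base class for all spheroquant errors."""


class ReadError(SpheroquantError):
    """An input file could not be read or decoded."""


class WriteError(SpheroquantError):
    """An output path could not be written."""


class EmptyStackError(SpheroquantError):
    """A TIFF file contained no image planes."""


class CalibrationError(SpheroquantError):
    """No pixel size available: neither file metadata nor a caller override."""


class SuffixCountError(SpheroquantError):
    """Fewer output suffixes than channels when splitting a stack."""


class ShapeError(SpheroquantError):
    """Images/label maps with mismatched dimensions were combined."""


class ParameterError(SpheroquantError):
    """An invalid or inconsistent parameter value."""


class InputError(SpheroquantError):
    """An input image violates basic validity (non-finite values etc.)."""


class NoSpheroidFoundError(SpheroquantError):
    """No connected component in the expected size window for the spheroid."""


class InvalidMaskError(SpheroquantError):
    """A spheroid mask with an empty perimeter or otherwise unusable geometry."""


class GeometryError(SpheroquantError):
    """Phantom canvas too small for the requested spheroid."""


class PackingError(SpheroquantError):
    """Nucleus dart-throwing could not satisfy the minimum separation."""


class DegenerateDistributionError(SpheroquantError):
    """Automatic (Otsu) thresholding asked for on <2 distinct values."""


class ConfigError(SpheroquantError):
    """A pipeline configuration that fails validation."""


class PipelineStageError(SpheroquantError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
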