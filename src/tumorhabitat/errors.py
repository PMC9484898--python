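"""Exception hierarchy for the habitat-analysis pipeline.

Every error raised by the package derives from :class:`TumorHabitatError`,
so callers can catch pipeline failures without shadowing programming errors.
"""


class TumorHabitatError(Exception):
    """Base class for all package errors."""


class ShapeMismatchError(TumorHabitatError):
    """Image and mask grids do not share dimensions."""


class EmptyROIError(TumorHabitatError):
    """The mask selects zero voxels."""


class DataError(TumorHabitatError):
    """Malformed or inconsistent input data (non-finite voxels, duplicate ids, bad labels)."""


class FormatError(TumorHabitatError):
    """A table or file does not match the expected schema."""


class InsufficientDataError(TumorHabitatError):
    """Too few observations for the requested operation."""


class DegenerateInputError(TumorHabitatError):
    """Input admits no valid solution (e.g. fewer distinct values than clusters)."""


class InvalidLabelingError(TumorHabitatError):
    """A cluster labeling violates its contract (empty cluster, length mismatch)."""


class IndexUndefinedError(TumorHabitatError):
    """A cluster-validity index is undefined for this labeling (e.g. K = 1)."""


class LabelError(TumorHabitatError):
    """Class labels are unusable (a class absent, single-class training set)."""


class StratificationError(TumorHabitatError):
    """A stratified split cannot be formed (a class has too few cases)."""


class SelectionEmptyError(TumorHabitatError):
    """Feature selection removed every feature."""


class SchemaError(TumorHabitatError):
    """A required feature/column is missing at prediction time."""


class GeometryError(TumorHabitatError):
    """Phantom geometry does not fit the requested grid."""


class ParameterError(TumorHabitatError):
    """An argument is outside its valid domain."""
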