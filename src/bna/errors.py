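"""Named exception types raised across the package."""


class BnaError(Exception):
    """Base class for all package-specific errors."""


class MontageError(BnaError):
    """Malformed montage: duplicate labels, bad coordinates, too few electrodes."""


class DegenerateMontageError(MontageError):
    """Electrode cloud is degenerate (e.g. coplanar through the head center)."""


class MetadataError(BnaError):
    """Required metadata line missing or unparseable in an ERP file."""


class SpacingError(BnaError):
    """Time axis is not uniformly spaced at the declared sampling rate."""


class SchemaVersionError(BnaError):
    """Model file carries an unknown schema version."""


class ModelParseError(BnaError):
    """Model file is truncated or otherwise unreadable."""


class InvalidConfigError(BnaError):
    """Simulation or pipeline configuration violates an invariant."""


class ComponentWindowError(InvalidConfigError):
    """A simulated component's latency falls outside the epoch window."""


class AllEpochsRejectedError(BnaError):
    """Artifact rejection removed every epoch."""


class FilterLengthError(BnaError):
    """Designed FIR filter is at least as long as the signal."""


class InterpolationError(BnaError):
    """Too few electrodes to fit the scalp interpolation surface."""


class GeometryMismatchError(BnaError):
    """Grid geometry of a model does not match the data being scored."""


class SingleClassError(BnaError):
    """Classifier training data contains only one class."""


class MissingCellError(BnaError):
    """Repeatability table has missing subject/visit cells."""


class SubjectMismatchError(BnaError):
    """Visits supplied for repeatability do not share the same subjects."""


class ColumnMismatchError(BnaError):
    """Feature columns do not align between training and scoring data."""
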