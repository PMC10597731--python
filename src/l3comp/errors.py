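"""Exception hierarchy shared across the pipeline.

Every error raised by the package derives from :class:`L3CompError`, so
callers can catch a single base class at the orchestration layer while
tests can assert the specific failure mode.
"""


class L3CompError(Exception):
    """Base class for all package errors."""


class InvalidInputError(L3CompError, ValueError):
    """An argument value violates a precondition (bad shape, empty group, ...)."""


class MetadataError(L3CompError):
    """A required DICOM tag is missing or carries an unusable value."""


class GeometryError(L3CompError):
    """Image geometry is not the expected 512 x 512 axial grid."""


class OrderingError(L3CompError):
    """Slice z-positions are not strictly monotone within a study."""


class DesignationError(L3CompError):
    """The mid-L3 designation matches zero or multiple slices."""


class InsufficientDataError(L3CompError):
    """Fewer slices / values than the operation needs."""


class AlignmentError(L3CompError):
    """Two arrays that must share a shape do not."""


class NoBodyError(L3CompError):
    """No body cross-section found in the image (all air)."""


class ParameterError(L3CompError, ValueError):
    """Phantom or configuration parameters violate their invariants."""


class ConfigError(L3CompError):
    """A run configuration failed validation."""
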