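"""Exception hierarchy.

Everything raised on purpose derives from :class:`NwuctError` so callers can
catch pipeline failures without swallowing programming errors.
"""


class NwuctError(Exception):
    """Base class for all errors raised by nwuct."""


class FormatError(NwuctError):
    """A file could not be read as the expected format."""


class DimensionalityError(FormatError):
    """An image does not have the expected number of dimensions."""


class SeriesError(FormatError):
    """A DICOM directory does not contain a single consistent series."""


class CalibrationError(FormatError):
    """DICOM slices lack the rescale tags needed to produce Hounsfield units."""


class ParameterError(NwuctError, ValueError):
    """An argument is outside its valid domain."""


class ForegroundError(NwuctError):
    """No foreground voxels above the air threshold."""


class ExtractionError(NwuctError):
    """Brain extraction found no candidate brain component."""


class MaskError(NwuctError):
    """A mask is empty or misaligned with its volume."""


class ConstructionError(NwuctError):
    """A synthetic atlas could not be built under the requested geometry."""


class SchemaError(NwuctError):
    """An atlas directory or code map violates the expected schema."""


class ComputationError(NwuctError):
    """A result is undefined for every region."""


class DegenerateOutcomeError(NwuctError):
    """The outcome column is constant; a classifier cannot be fit."""


class DegenerateLabelError(NwuctError):
    """Labels contain a single class; ranking metrics are undefined."""


class CollinearityError(NwuctError):
    """The design matrix is rank deficient."""


class PairingError(NwuctError):
    """Paired score vectors have mismatched lengths."""
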